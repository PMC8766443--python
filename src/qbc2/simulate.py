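"""Forward simulator for a split-pool DNA-barcoded-antibody experiment.

The simulator produces what a real run produces — paired-end FASTQ — plus
the ground truth a real run never has: which cell each molecule came from,
which wells the cell visited, and the true antigen copy numbers.

Stages mirror the bench protocol:

1. ``simulate_cells``      — samples, cell types, antibody staining,
                             hashtag sample labels, spike-in control cells.
2. ``simulate_splitpool``  — random well assignment over two ligation
                             rounds and one PCR round; per-molecule ligation
                             failure, splint-blocking failure (late-spike
                             cells illegitimately gaining a round-1 barcode),
                             and antibody swapping between cells.
3. ``simulate_reads``      — PCR duplication as per-molecule read
                             multiplicity, i.i.d. substitution sequencing
                             errors, gzip FASTQ output plus truth TSVs.

Antigen copy numbers are log-normal around per-type means with a Poisson
sampling layer, so low-abundance antibodies produce genuine zeros.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (ANTIBODY, HASHTAG, ROUND1, ROUND2, ROUND3, UMI,
                     AntibodyPanel, BarcodeSchema, HashtagCode, validate_schema)

FLAG_NONE = "none"
FLAG_HT2 = "ht2_only"
FLAG_HT3 = "ht3_late_spike"

_BASE_LUT = np.frombuffer(b"ACGT", dtype=np.uint8)
_BASE_INV = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _BASE_INV[_b] = _i


class ConfigError(ValueError):
    pass


@dataclass
class CellType:
    """Mean antibody molecule counts for one cell population.

    ``mean_counts`` maps antibody name -> expected bound molecules; absent
    antibodies fall back to the ambient background.  ``dispersion`` is the
    log-normal sigma (natural-log scale) of cell-to-cell variation.
    """

    name: str
    mean_counts: dict[str, float]
    dispersion: float = 0.35


@dataclass
class SimConfig:
    panel: AntibodyPanel
    cell_types: dict[str, CellType]
    sample_sizes: dict[str, int]
    sample_composition: dict[str, dict[str, float]]
    hashtag_code: HashtagCode
    hashtag_mean: float = 30.0
    control_hashtag_mean: float = 120.0
    background_mean: float = 0.3
    ht2_spike_fraction: float = 0.05
    ht3_spike_fraction: float = 0.05
    ht2_spike_n: int | None = None   # absolute override (controls-only designs)
    ht3_spike_n: int | None = None
    ht2_hashtag: str = "HT2"
    ht3_hashtag: str = "HT3"
    ligation_success_prob: tuple[float, float, float] = (1.0, 1.0, 1.0)
    blocking_failure_prob: float = 0.0
    swap_rate: float = 0.0
    pcr_cycles: int = 14  # bench metadata; duplication is mean_reads_per_molecule
    mean_reads_per_molecule: float = 1.0
    error_rate: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if not self.cell_types:
            raise ConfigError("at least one cell type must be defined")
        probs = [self.ht2_spike_fraction, self.ht3_spike_fraction,
                 self.blocking_failure_prob, self.swap_rate, self.error_rate,
                 *self.ligation_success_prob]
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        names = set(self.panel.names)
        for tag in (self.ht2_hashtag, self.ht3_hashtag):
            if tag not in names:
                raise ConfigError(f"control hashtag {tag!r} missing from panel")
        for sample, comp in self.sample_composition.items():
            unknown = set(comp) - set(self.cell_types)
            if unknown:
                raise ConfigError(f"sample {sample}: unknown cell types {unknown}")
            if abs(sum(comp.values()) - 1.0) > 1e-9:
                raise ConfigError(f"sample {sample}: composition must sum to 1")
        for sample, sub in self.hashtag_code.mapping.items():
            if not sub <= names:
                raise ConfigError(f"sample {sample}: code hashtags not in panel")

    def rng(self, stage: int) -> np.random.Generator:
        # independent deterministic stream per stage
        return np.random.default_rng([int(self.seed), stage])


@dataclass
class CellTruth:
    cell_id: str
    sample_id: str
    cell_type: str
    control_flag: str
    counts: np.ndarray  # true molecule counts, aligned to panel order
    r1_well: int | None = None
    r2_well: int | None = None
    r3_well: int | None = None
    triple: tuple[str, str, str] | None = None

    def antigen_counts(self, panel: AntibodyPanel) -> dict[str, int]:
        return dict(zip(panel.names, (int(c) for c in self.counts)))


@dataclass
class SimOutput:
    r1_fastq: Path
    r2_fastq: Path
    cells_tsv: Path
    molecules_tsv: Path
    n_reads: int


# ---------------------------------------------------------------------------
# stage 1: cells
# ---------------------------------------------------------------------------

def _draw_counts(means: np.ndarray, sigmas: np.ndarray,
                 rng: np.random.Generator) -> np.ndarray:
    """Poisson(lognormal) counts: integer, overdispersed, zero-capable."""
    lam = means * np.exp(rng.normal(0.0, sigmas[:, None], size=means.shape))
    return rng.poisson(lam)


def simulate_cells(config: SimConfig) -> list[CellTruth]:
    """Generate stained cells for every sample plus spike-in controls.

    Regular cells carry their type's marker profile plus exactly the
    hashtag subset of their sample; HT2 controls (added before round 1)
    carry only the HT2 hashtag; HT3 controls (added after round 1) carry
    only the HT3 hashtag and will lack a round-1 well downstream.
    """
    config.validate()
    rng = config.rng(0)
    panel = config.panel
    names = panel.names
    n_ab = len(names)
    cells: list[CellTruth] = []

    def background(n: int) -> np.ndarray:
        return rng.poisson(config.background_mean, size=(n, n_ab))

    for sample, n in config.sample_sizes.items():
        if n == 0:
            continue
        comp = config.sample_composition[sample]
        type_names = list(comp)
        type_idx = rng.choice(len(type_names), size=n, p=list(comp.values()))
        mean_rows = np.zeros((len(type_names), n_ab))
        sig = np.zeros(len(type_names))
        code = config.hashtag_code.encode(sample)
        for t, tname in enumerate(type_names):
            ct = config.cell_types[tname]
            sig[t] = ct.dispersion
            for j, ab in enumerate(names):
                m = ct.mean_counts.get(ab, 0.0)
                if ab in code:
                    m = max(m, config.hashtag_mean)
                mean_rows[t, j] = m
        counts = _draw_counts(mean_rows[type_idx], sig[type_idx], rng)
        counts += background(n)
        for i in range(n):
            cells.append(CellTruth(
                cell_id=f"c{len(cells):06d}", sample_id=sample,
                cell_type=type_names[type_idx[i]], control_flag=FLAG_NONE,
                counts=counts[i]))

    n_regular = len(cells)
    for flag, frac, override, tag in (
        (FLAG_HT2, config.ht2_spike_fraction, config.ht2_spike_n,
         config.ht2_hashtag),
        (FLAG_HT3, config.ht3_spike_fraction, config.ht3_spike_n,
         config.ht3_hashtag),
    ):
        n_spike = override if override is not None else int(round(frac * n_regular))
        if n_spike == 0:
            continue
        j = names.index(tag)
        means = np.zeros((n_spike, n_ab))
        means[:, j] = config.control_hashtag_mean
        counts = _draw_counts(means, np.full(n_spike, 0.35), rng)
        counts += background(n_spike)
        for i in range(n_spike):
            cells.append(CellTruth(
                cell_id=f"c{len(cells):06d}", sample_id="control",
                cell_type=flag, control_flag=flag, counts=counts[i]))
    return cells


# ---------------------------------------------------------------------------
# stage 2: split-pool labeling
# ---------------------------------------------------------------------------

def simulate_splitpool(cells: list[CellTruth], schema: BarcodeSchema,
                       config: SimConfig) -> pd.DataFrame:
    """Assign wells and label every antibody molecule.

    Returns a molecule table with one row per antibody molecule:
    ``cell_index`` (staining origin), ``host_index`` (the cell whose well
    path the molecule followed; differs from origin when swapped),
    ``antibody``, ``umi`` (integer code) and the three well indices
    (−1 = barcode missing: ligation failed or cell joined late).
    """
    report = validate_schema(schema)
    if not report.ok:
        raise ConfigError("invalid schema: " + "; ".join(report.violations))
    rng = config.rng(1)
    n = len(cells)
    w1, w2, w3 = schema.wells_per_round
    r1 = rng.integers(0, w1, size=n)
    r2 = rng.integers(0, w2, size=n)
    r3 = rng.integers(0, w3, size=n)
    is_ht3 = np.array([c.control_flag == FLAG_HT3 for c in cells])
    r1[is_ht3] = -1  # joined after round 1

    for i, cell in enumerate(cells):
        cell.r1_well = None if is_ht3[i] else int(r1[i])
        cell.r2_well = int(r2[i])
        cell.r3_well = int(r3[i])
        cell.triple = (
            None if is_ht3[i] else schema.whitelist_r1[r1[i]],
            schema.whitelist_r2[r2[i]],
            schema.whitelist_r3[r3[i]],
        )

    counts = np.vstack([c.counts for c in cells])
    n_ab = counts.shape[1]
    cell_idx = np.repeat(np.arange(n), counts.sum(axis=1))
    ab_idx = np.repeat(np.tile(np.arange(n_ab), n), counts.ravel())
    m = cell_idx.size

    # antibody dissociation/swap: the molecule relocates to a random other
    # cell before barcoding and follows that cell's entire well path,
    # depositing foreign signal on the host cell's called barcode
    host_idx = cell_idx.copy()
    if config.swap_rate > 0 and n > 1:
        swap = rng.random(m) < config.swap_rate
        k = int(swap.sum())
        host_idx[swap] = (cell_idx[swap] + 1 + rng.integers(0, n - 1, size=k)) % n

    m_r1 = r1[host_idx].astype(np.int64)
    # splint-blocking failure: a late-spike molecule picks up a stray
    # round-1 barcode from the pooled mix
    if config.blocking_failure_prob > 0:
        late = m_r1 == -1
        leak = late & (rng.random(m) < config.blocking_failure_prob)
        m_r1[leak] = rng.integers(0, w1, size=int(leak.sum()))
    m_r2 = r2[host_idx].astype(np.int64)
    m_r3 = r3[host_idx].astype(np.int64)
    p1, p2, p3 = config.ligation_success_prob
    if p1 < 1.0:
        m_r1[rng.random(m) >= p1] = -1
    if p2 < 1.0:
        m_r2[rng.random(m) >= p2] = -1
    if p3 < 1.0:
        m_r3[rng.random(m) >= p3] = -1

    umi_len = schema.umi_length
    umis = rng.integers(0, 4 ** umi_len, size=m)
    panel_names = pd.Categorical.from_codes(ab_idx, categories=config.panel.names)
    return pd.DataFrame({
        "molecule_id": np.arange(m),
        "cell_index": cell_idx,
        "host_index": host_idx,
        "antibody": panel_names,
        "umi": umis,
        "r1_well": m_r1,
        "r2_well": m_r2,
        "r3_well": m_r3,
    })


# ---------------------------------------------------------------------------
# stage 3: reads
# ---------------------------------------------------------------------------

def _encode_seqs(seqs) -> np.ndarray:
    """(n, L) uint8 array of ASCII codes from equal-length strings."""
    return np.frombuffer("".join(seqs).encode(), dtype=np.uint8).reshape(
        len(seqs), -1)


def umi_to_str(codes: np.ndarray, length: int) -> np.ndarray:
    """Vectorized integer-code -> DNA-string decoding (MSB first)."""
    codes = np.asarray(codes, dtype=np.int64)
    digits = np.empty((codes.size, length), dtype=np.uint8)
    for j in range(length):
        digits[:, j] = (codes >> (2 * (length - 1 - j))) & 3
    flat = _BASE_LUT[digits].tobytes().decode()
    return np.array([flat[i * length:(i + 1) * length]
                     for i in range(codes.size)])


def _apply_substitutions(arr: np.ndarray, rate: float,
                         rng: np.random.Generator) -> None:
    if rate <= 0:
        return
    mask = rng.random(arr.shape) < rate
    k = int(mask.sum())
    if k == 0:
        return
    idx = _BASE_INV[arr[mask]]
    arr[mask] = _BASE_LUT[(idx + rng.integers(1, 4, size=k)) % 4]


def _write_fastq_gz(path: Path, names: list[bytes], seqs: np.ndarray) -> None:
    qual = b"I" * seqs.shape[1]
    with gzip.open(path, "wb", compresslevel=4) as fh:
        chunk: list[bytes] = []
        for i, name in enumerate(names):
            chunk.append(b"@" + name + b"\n" + seqs[i].tobytes() + b"\n+\n"
                         + qual + b"\n")
            if len(chunk) == 20000:
                fh.write(b"".join(chunk))
                chunk.clear()
        if chunk:
            fh.write(b"".join(chunk))


def simulate_reads(molecules: pd.DataFrame, cells: list[CellTruth],
                   schema: BarcodeSchema, config: SimConfig,
                   out_dir: str | Path) -> SimOutput:
    """Emit paired-end FASTQ plus truth tables.

    Molecules missing any of the three well barcodes never amplify and are
    dropped.  Each surviving molecule yields a geometric number of read
    pairs (mean ``mean_reads_per_molecule``) sharing its UMI; substitution
    errors are applied i.i.d. per base.  Quality strings are constant.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = config.rng(2)

    complete = ((molecules["r1_well"] >= 0) & (molecules["r2_well"] >= 0)
                & (molecules["r3_well"] >= 0)).to_numpy()
    seq = molecules.loc[complete]
    n_mol = len(seq)
    mean_reads = config.mean_reads_per_molecule
    if mean_reads <= 1.0:
        dups = np.ones(n_mol, dtype=np.int64)
    else:
        dups = rng.geometric(1.0 / mean_reads, size=n_mol)
    rep = np.repeat(np.arange(n_mol), dups)
    n_reads = rep.size

    # read 1: well barcodes + linkers over inert padding
    r1_arr = np.full((n_reads, schema.read1_length), ord("A"), dtype=np.uint8)
    wl_arrays = {ROUND1: _encode_seqs(schema.whitelist_r1),
                 ROUND2: _encode_seqs(schema.whitelist_r2),
                 ROUND3: _encode_seqs(schema.whitelist_r3)}
    well_cols = {ROUND1: "r1_well", ROUND2: "r2_well", ROUND3: "r3_well"}
    for seg in schema.segments_read1:
        if seg.sequence is not None:
            r1_arr[:, seg.offset:seg.end] = np.frombuffer(
                seg.sequence.encode(), dtype=np.uint8)
        elif seg.role in wl_arrays:
            wells = seq[well_cols[seg.role]].to_numpy()[rep]
            r1_arr[:, seg.offset:seg.end] = wl_arrays[seg.role][wells]

    # read 2: antibody barcode + UMI
    r2_arr = np.full((n_reads, schema.read2_length), ord("A"), dtype=np.uint8)
    ab_codes = seq["antibody"].cat.codes.to_numpy()[rep]
    ab_arr = _encode_seqs(config.panel.barcodes)
    seg_ab = schema.segment(ANTIBODY)
    r2_arr[:, seg_ab.offset:seg_ab.end] = ab_arr[ab_codes]
    seg_umi = schema.segment(UMI)
    umi_codes = seq["umi"].to_numpy()[rep]
    for j in range(seg_umi.length):
        shift = 2 * (seg_umi.length - 1 - j)
        r2_arr[:, seg_umi.offset + j] = _BASE_LUT[(umi_codes >> shift) & 3]

    _apply_substitutions(r1_arr, config.error_rate, rng)
    _apply_substitutions(r2_arr, config.error_rate, rng)

    mol_ids = seq["molecule_id"].to_numpy()[rep]
    dup_no = np.concatenate([np.arange(d) for d in dups]) if n_reads else \
        np.array([], dtype=int)
    names = [b"mol%d:%d" % (mid, j) for mid, j in zip(mol_ids, dup_no)]
    r1_path, r2_path = out / "reads_R1.fastq.gz", out / "reads_R2.fastq.gz"
    _write_fastq_gz(r1_path, names, r1_arr)
    _write_fastq_gz(r2_path, names, r2_arr)

    cells_tsv = out / "cells.tsv"
    cell_rows = []
    for c in cells:
        cell_rows.append({
            "cell_id": c.cell_id, "sample_id": c.sample_id,
            "cell_type": c.cell_type, "control_flag": c.control_flag,
            "r1_well": -1 if c.r1_well is None else c.r1_well,
            "r2_well": c.r2_well, "r3_well": c.r3_well,
            "triple": triple_key(c.triple),
            **{f"n_{name}": int(v) for name, v in
               zip(config.panel.names, c.counts)},
        })
    pd.DataFrame(cell_rows).to_csv(cells_tsv, sep="\t", index=False)

    mol_out = molecules.copy()
    mol_out["umi_seq"] = umi_to_str(mol_out["umi"].to_numpy(),
                                    schema.umi_length)
    mol_out["sequenced"] = complete
    reads_per_mol = np.zeros(len(molecules), dtype=np.int64)
    reads_per_mol[np.flatnonzero(complete)] = dups
    mol_out["n_reads"] = reads_per_mol
    mol_out["cell_id"] = [cells[i].cell_id for i in mol_out["cell_index"]]
    molecules_tsv = out / "molecules.tsv"
    mol_out.to_csv(molecules_tsv, sep="\t", index=False)

    return SimOutput(r1_path, r2_path, cells_tsv, molecules_tsv, n_reads)


def triple_key(triple) -> str:
    """Canonical string key for a well-barcode triple; missing parts -> '*'."""
    if triple is None:
        return "*"
    return "-".join("*" if t is None else t for t in triple)


def truth_count_matrix(cells: list[CellTruth],
                       panel: AntibodyPanel) -> pd.DataFrame:
    """True (pre-sequencing) molecule counts, cells x antibodies."""
    return pd.DataFrame(np.vstack([c.counts for c in cells]),
                        index=[c.cell_id for c in cells], columns=panel.names)


def counts_from_truth(cells: list[CellTruth], panel: AntibodyPanel):
    """Package true molecule counts as a CountMatrix (cell ids as barcodes).

    Bypasses sequencing entirely — handy for testing the quantification
    and analysis layers against known ground truth.
    """
    import scipy.sparse as sp

    from .demux import CountMatrix

    matrix = sp.csr_matrix(np.vstack([c.counts for c in cells]),
                           dtype=np.int64)
    features = pd.DataFrame({"name": panel.names,
                             "class": [c for _, _, c in panel.entries]})
    return CountMatrix(matrix, [c.cell_id for c in cells], features)


def run_simulation(schema: BarcodeSchema, config: SimConfig,
                   out_dir: str | Path):
    """Convenience wrapper: cells -> split-pool -> reads, all to ``out_dir``."""
    cells = simulate_cells(config)
    molecules = simulate_splitpool(cells, schema, config)
    output = simulate_reads(molecules, cells, schema, config, out_dir)
    return cells, molecules, output
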