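"""Demultiplexer: paired-end reads -> single cells -> antibody UMI counts.

Read 1 carries the three well barcodes that jointly identify a cell; read 2
carries the antibody barcode and the UMI.  Every read pair is sliced at the
schema's segment offsets, each barcode is error-corrected against its
whitelist (unique nearest entry within the correction radius; ties and
out-of-radius observations are rejected, never guessed), reads sharing a
corrected barcode triple are grouped into one cell, and PCR duplicates are
removed by collapsing UMIs per (cell, antibody).

Rejected reads are tallied in a discard ledger by the first stage that
failed, so input read counts are always conserved.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from pathlib import Path
from collections import Counter, defaultdict
from typing import Iterable

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .schema import (ANTIBODY, ROUND1, ROUND2, ROUND3, UMI,
                     AntibodyPanel, BarcodeSchema)

LEDGER_KEYS = ("input_pairs", "truncated", "round1_barcode", "round2_barcode",
               "round3_barcode", "antibody_barcode", "low_umi_cell", "assigned")


class ReadTooShortError(ValueError):
    """Read shorter than the span the schema requires."""


@dataclass(slots=True)
class RawRecord:
    """Fields sliced from one read pair (optionally whitelist-corrected).

    A corrected record carries ``None`` in any field whose correction was
    rejected.
    """

    name: str
    r1_bc: str | None
    r2_bc: str | None
    r3_bc: str | None
    antibody: str | None
    umi: str


def parse_read_pair(r1_seq: str, r2_seq: str, schema: BarcodeSchema,
                    name: str = "") -> RawRecord:
    """Slice the schema's segments out of a read pair (no correction)."""
    need1 = max(s.end for s in schema.segments_read1)
    need2 = max(s.end for s in schema.segments_read2)
    if len(r1_seq) < need1 or len(r2_seq) < need2:
        raise ReadTooShortError(
            f"truncated: read lengths ({len(r1_seq)}, {len(r2_seq)}) below "
            f"required spans ({need1}, {need2})")
    return RawRecord(
        name=name,
        r1_bc=schema.segment(ROUND1).slice(r1_seq),
        r2_bc=schema.segment(ROUND2).slice(r1_seq),
        r3_bc=schema.segment(ROUND3).slice(r1_seq),
        antibody=schema.segment(ANTIBODY).slice(r2_seq),
        umi=schema.segment(UMI).slice(r2_seq),
    )


def correct_barcode(observed: str, whitelist, max_mismatch: int = 1) -> str | None:
    """Correct one barcode against a whitelist.

    Returns the unique whitelist entry within Hamming distance
    ``max_mismatch``, or None when no entry is close enough or two entries
    tie at the minimum distance (ambiguity is rejected, not broken).
    Non-ACGT characters (e.g. N) count as mismatches to every base.
    """
    whitelist = tuple(whitelist)
    if whitelist and len(observed) != len(whitelist[0]):
        raise ValueError(
            f"observed length {len(observed)} != whitelist length "
            f"{len(whitelist[0])}")
    if observed in whitelist:
        return observed
    best, best_d, ties = None, max_mismatch + 1, 0
    for entry in whitelist:
        d = sum(a != b for a, b in zip(observed, entry))
        if d < best_d:
            best, best_d, ties = entry, d, 1
        elif d == best_d:
            ties += 1
    return best if best is not None and ties == 1 else None


def _correct_uniques(uniques: np.ndarray, whitelist,
                     max_mismatch: int) -> np.ndarray:
    """Vectorized correction of an array of distinct observed strings.

    Returns an object array of corrected strings (None where rejected).
    """
    wl = list(whitelist)
    wl_set = {w: w for w in wl}
    out = np.array([wl_set.get(u) for u in uniques], dtype=object)
    miss = np.flatnonzero([o is None for o in out])
    if miss.size == 0 or not wl:
        return out
    L = len(wl[0])
    obs = np.frombuffer("".join(uniques[i] for i in miss).encode("latin1"),
                        dtype=np.uint8).reshape(miss.size, L)
    wl_arr = np.frombuffer("".join(wl).encode(), dtype=np.uint8).reshape(
        len(wl), L)
    dist = (obs[:, None, :] != wl_arr[None, :, :]).sum(axis=2)
    dmin = dist.min(axis=1)
    n_at_min = (dist == dmin[:, None]).sum(axis=1)
    ok = (dmin <= max_mismatch) & (n_at_min == 1)
    arg = dist.argmin(axis=1)
    for row, i in enumerate(miss):
        if ok[row]:
            out[i] = wl[arg[row]]
    return out


# ---------------------------------------------------------------------------
# UMI collapse
# ---------------------------------------------------------------------------

def collapse_umis(umis, method: str = "directional",
                  umi_mismatch: int = 1) -> int:
    """Number of distinct molecules among the observed UMI copies.

    ``exact``: distinct strings.  ``directional``: connected components
    after merging B into A whenever Hamming(A, B) <= umi_mismatch and
    count(A) >= 2*count(B) - 1 — the standard network rule that absorbs
    single-error PCR/sequencing satellites into their abundant parent.
    """
    counter = umis if isinstance(umis, Counter) else Counter(umis)
    if not counter:
        return 0
    if method == "exact":
        return len(counter)
    if method != "directional":
        raise ValueError(f"unknown collapse method {method!r}")
    uniq = sorted(counter, key=lambda u: (-counter[u], u))
    k = len(uniq)
    if k == 1:
        return 1
    lengths = {len(u) for u in uniq}
    if len(lengths) != 1:
        raise ValueError("UMIs must have equal length")
    parent = list(range(k))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    arr = np.frombuffer("".join(uniq).encode(), dtype=np.uint8).reshape(k, -1)
    counts = np.array([counter[u] for u in uniq])
    for i in range(k):
        d = (arr[i + 1:] != arr[i]).sum(axis=1)
        for off in np.flatnonzero(d <= umi_mismatch):
            j = i + 1 + off
            if counts[i] >= 2 * counts[j] - 1:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    return len({find(i) for i in range(k)})


# ---------------------------------------------------------------------------
# cell calling
# ---------------------------------------------------------------------------

@dataclass
class CellCall:
    """One called cell: a corrected barcode triple with its UMI evidence."""

    triple: tuple[str, str, str]
    umis: dict[str, Counter] = field(default_factory=dict)

    @property
    def key(self) -> str:
        return "-".join(self.triple)

    def add(self, antibody: str, umi: str) -> None:
        self.umis.setdefault(antibody, Counter())[umi] += 1

    def raw_reads(self) -> int:
        return sum(sum(c.values()) for c in self.umis.values())

    def collapsed_counts(self, method: str = "directional",
                         umi_mismatch: int = 1) -> dict[str, int]:
        return {ab: collapse_umis(c, method, umi_mismatch)
                for ab, c in self.umis.items()}

    def total_umis(self, method: str = "directional",
                   umi_mismatch: int = 1) -> int:
        return sum(self.collapsed_counts(method, umi_mismatch).values())


def call_cells(records: Iterable[RawRecord], min_umi: int = 10,
               collapse: str = "directional", umi_mismatch: int = 1,
               ledger: dict | None = None) -> tuple[list[CellCall], dict]:
    """Group corrected records into cells keyed by their barcode triple.

    Records with any rejected field go to the discard ledger; called cells
    whose total collapsed UMI count falls below ``min_umi`` are dropped
    (their reads are tallied under ``low_umi_cell``).
    """
    ledger = ledger if ledger is not None else {k: 0 for k in LEDGER_KEYS}
    groups: dict[tuple[str, str, str], CellCall] = {}
    for rec in records:
        ledger["input_pairs"] += 1
        if rec.r1_bc is None:
            ledger["round1_barcode"] += 1
            continue
        if rec.r2_bc is None:
            ledger["round2_barcode"] += 1
            continue
        if rec.r3_bc is None:
            ledger["round3_barcode"] += 1
            continue
        if rec.antibody is None:
            ledger["antibody_barcode"] += 1
            continue
        key = (rec.r1_bc, rec.r2_bc, rec.r3_bc)
        call = groups.get(key)
        if call is None:
            call = groups[key] = CellCall(key)
        call.add(rec.antibody, rec.umi)
        ledger["assigned"] += 1
    cells = []
    for call in groups.values():
        if call.total_umis(collapse, umi_mismatch) >= min_umi:
            cells.append(call)
        else:
            ledger["low_umi_cell"] += call.raw_reads()
            ledger["assigned"] -= call.raw_reads()
    cells.sort(key=lambda c: c.key)
    return cells, ledger


# ---------------------------------------------------------------------------
# count matrix
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """Sparse cells x antibodies UMI-collapsed counts."""

    matrix: sp.csr_matrix
    barcodes: list[str]              # triple keys, "r1-r2-r3"
    features: pd.DataFrame           # columns: name, class

    def __post_init__(self) -> None:
        assert self.matrix.shape == (len(self.barcodes), len(self.features))

    @property
    def antibody_names(self) -> list[str]:
        return list(self.features["name"])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix.toarray(), index=self.barcodes,
                            columns=self.antibody_names)


def build_count_matrix(calls: list[CellCall], panel: AntibodyPanel,
                       collapse: str = "directional",
                       umi_mismatch: int = 1) -> CountMatrix:
    names = panel.names
    col = {n: j for j, n in enumerate(names)}
    rows, cols, data = [], [], []
    barcodes = []
    for i, call in enumerate(calls):
        barcodes.append(call.key)
        for ab, n in call.collapsed_counts(collapse, umi_mismatch).items():
            if n:
                rows.append(i)
                cols.append(col[ab])
                data.append(n)
    matrix = sp.csr_matrix((data, (rows, cols)),
                           shape=(len(calls), len(names)), dtype=np.int64)
    features = pd.DataFrame({"name": names,
                             "class": [c for _, _, c in panel.entries]})
    return CountMatrix(matrix, barcodes, features)


def write_count_matrix(cm: CountMatrix, out_dir: str | Path) -> Path:
    """Matrix Market triplet: matrix.mtx + barcodes.tsv + features.tsv."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), cm.matrix.tocoo(),
                     field="integer")
    pd.Series(cm.barcodes).to_csv(out / "barcodes.tsv", sep="\t", index=False,
                                  header=False)
    cm.features.to_csv(out / "features.tsv", sep="\t", index=False,
                       header=False)
    return out


def read_count_matrix(in_dir: str | Path) -> CountMatrix:
    ind = Path(in_dir)
    matrix = sp.csr_matrix(scipy.io.mmread(str(ind / "matrix.mtx")),
                           dtype=np.int64)
    bc_path = ind / "barcodes.tsv"
    barcodes = (pd.read_csv(bc_path, sep="\t", header=None)[0].tolist()
                if bc_path.stat().st_size else [])
    features = pd.read_csv(ind / "features.tsv", sep="\t", header=None,
                           names=["name", "class"])
    return CountMatrix(matrix, barcodes, features)


def write_ledger(ledger: dict, path: str | Path) -> None:
    pd.Series(ledger, name="reads").rename_axis("reason").to_csv(
        path, sep="\t")


# ---------------------------------------------------------------------------
# FASTQ -> count matrix
# ---------------------------------------------------------------------------

def _open_text(path: str | Path):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def demux_fastq(r1_path: str | Path, r2_path: str | Path,
                schema: BarcodeSchema, panel: AntibodyPanel,
                min_umi: int = 10, collapse: str = "directional",
                umi_mismatch: int = 1,
                max_mismatch: int | None = None
                ) -> tuple[CountMatrix, dict]:
    """Full demultiplex of a paired FASTQ run.

    Correction is vectorized over the distinct observed strings per
    segment, so exact-match reads (the vast majority) cost one dictionary
    lookup.  Returns the UMI-collapsed count matrix and the discard ledger.
    """
    radius = schema.correction_radius if max_mismatch is None else max_mismatch
    need1 = max(s.end for s in schema.segments_read1)
    need2 = max(s.end for s in schema.segments_read2)
    segs = {role: schema.segment(role)
            for role in (ROUND1, ROUND2, ROUND3, ANTIBODY, UMI)}

    names: list[str] = []
    fields: dict[str, list[str]] = {r: [] for r in segs}
    n_truncated = 0
    n_input = 0
    with _open_text(r1_path) as f1, _open_text(r2_path) as f2:
        for (n1, s1, _), (_, s2, _) in zip(FastqGeneralIterator(f1),
                                           FastqGeneralIterator(f2)):
            n_input += 1
            if len(s1) < need1 or len(s2) < need2:
                n_truncated += 1
                continue
            names.append(n1)
            for role, seg in segs.items():
                fields[role].append(s1[seg.offset:seg.end]
                                    if role in (ROUND1, ROUND2, ROUND3)
                                    else s2[seg.offset:seg.end])

    corrected: dict[str, np.ndarray] = {}
    for role, wl in ((ROUND1, schema.whitelist_r1),
                     (ROUND2, schema.whitelist_r2),
                     (ROUND3, schema.whitelist_r3),
                     (ANTIBODY, panel.barcodes)):
        codes, uniques = pd.factorize(np.asarray(fields[role], dtype=object))
        fixed = (_correct_uniques(uniques, wl, radius)
                 if len(uniques) else np.array([], dtype=object))
        if role == ANTIBODY:  # report antibodies by name, not barcode
            seq_to_name = {s: n for n, s, _ in panel.entries}
            fixed = np.array([None if s is None else seq_to_name[s]
                              for s in fixed], dtype=object)
        corrected[role] = fixed[codes] if len(codes) else np.array([], dtype=object)

    records = (RawRecord(name, r1, r2, r3, ab, umi)
               for name, r1, r2, r3, ab, umi in zip(
                   names, corrected[ROUND1], corrected[ROUND2],
                   corrected[ROUND3], corrected[ANTIBODY], fields[UMI]))
    ledger = {k: 0 for k in LEDGER_KEYS}
    calls, ledger = call_cells(records, min_umi, collapse, umi_mismatch,
                               ledger)
    ledger["truncated"] = n_truncated
    ledger["input_pairs"] = n_input
    cm = build_count_matrix(calls, panel, collapse, umi_mismatch)
    return cm, ledger
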