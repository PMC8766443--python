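"""Barcode architecture: read layout, whitelists, antibody panel, hashtag sample code.

A split-pool run tags every antibody-bound oligo with three well barcodes
(two ligation rounds plus one PCR round).  Read 1 carries the three well
barcodes, read 2 the antibody barcode and the UMI.  This module defines the
layout contract used by both the simulator and the demultiplexer, and the
combinatorial hashtag code that maps pooled samples to subsets of hashtag
antibodies.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

ALPHABET = "ACGT"

# segment roles
ROUND1 = "round1_well"
ROUND2 = "round2_well"
ROUND3 = "round3_pcr"
LINKER = "linker"
ANTIBODY = "antibody_barcode"
UMI = "umi"

MARKER = "marker"
HASHTAG = "hashtag"
ISOTYPE = "isotype_control"


@dataclass(frozen=True)
class Segment:
    """A fixed-position slice of a read.

    ``sequence`` is set for constant segments (linkers); variable segments
    (barcodes, UMI) leave it None.
    """

    role: str
    offset: int
    length: int
    sequence: str | None = None

    @property
    def end(self) -> int:
        return self.offset + self.length

    def slice(self, read: str) -> str:
        return read[self.offset : self.end]


@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __bool__(self) -> bool:  # truthiness == usable
        return self.ok


@dataclass
class BarcodeSchema:
    """Read-layout contract: where each barcode lives and what it may be."""

    segments_read1: list[Segment]
    segments_read2: list[Segment]
    whitelist_r1: tuple[str, ...]
    whitelist_r2: tuple[str, ...]
    whitelist_r3: tuple[str, ...]
    read1_length: int = 100
    read2_length: int = 50
    correction_radius: int = 1

    def segment(self, role: str) -> Segment:
        for seg in itertools.chain(self.segments_read1, self.segments_read2):
            if seg.role == role:
                return seg
        raise KeyError(f"no segment with role {role!r}")

    def whitelist(self, role: str) -> tuple[str, ...]:
        return {ROUND1: self.whitelist_r1, ROUND2: self.whitelist_r2,
                ROUND3: self.whitelist_r3}[role]

    @property
    def wells_per_round(self) -> tuple[int, int, int]:
        return (len(self.whitelist_r1), len(self.whitelist_r2), len(self.whitelist_r3))

    @property
    def barcode_capacity(self) -> int:
        """Total number of distinct well-barcode triples (m = w1*w2*w3)."""
        w1, w2, w3 = self.wells_per_round
        return w1 * w2 * w3

    @property
    def umi_length(self) -> int:
        return self.segment(UMI).length

    # -- serialization -------------------------------------------------

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        doc = {
            "read1_length": self.read1_length,
            "read2_length": self.read2_length,
            "correction_radius": self.correction_radius,
            "segments_read1": [
                {"role": s.role, "offset": s.offset, "length": s.length,
                 **({"sequence": s.sequence} if s.sequence else {})}
                for s in self.segments_read1
            ],
            "segments_read2": [
                {"role": s.role, "offset": s.offset, "length": s.length}
                for s in self.segments_read2
            ],
        }
        (out / "schema.yaml").write_text(yaml.safe_dump(doc, sort_keys=False))
        for name, wl in (("whitelist_r1.txt", self.whitelist_r1),
                         ("whitelist_r2.txt", self.whitelist_r2),
                         ("whitelist_r3.txt", self.whitelist_r3)):
            (out / name).write_text("\n".join(wl) + "\n")

    @classmethod
    def load(cls, in_dir: str | Path) -> "BarcodeSchema":
        ind = Path(in_dir)
        doc = yaml.safe_load((ind / "schema.yaml").read_text())
        wls = [tuple((ind / f"whitelist_r{i}.txt").read_text().split())
               for i in (1, 2, 3)]
        return cls(
            segments_read1=[Segment(d["role"], d["offset"], d["length"],
                                    d.get("sequence")) for d in doc["segments_read1"]],
            segments_read2=[Segment(d["role"], d["offset"], d["length"])
                            for d in doc["segments_read2"]],
            whitelist_r1=wls[0], whitelist_r2=wls[1], whitelist_r3=wls[2],
            read1_length=doc["read1_length"], read2_length=doc["read2_length"],
            correction_radius=doc["correction_radius"],
        )


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    return sum(x != y for x, y in zip(a, b))


def min_pairwise_hamming(whitelist) -> int:
    """Smallest Hamming distance between any two whitelist entries.

    A whitelist supports unambiguous correction at radius r iff the result
    is >= 2r + 1.
    """
    entries = sorted(set(whitelist))
    if len(entries) < 2:
        raise ValueError("min_pairwise_hamming needs at least 2 distinct entries")
    lengths = {len(e) for e in entries}
    if len(lengths) != 1:
        raise ValueError("whitelist entries must have equal length")
    arr = np.frombuffer("".join(entries).encode(), dtype=np.uint8)
    arr = arr.reshape(len(entries), -1)
    # pairwise distances via broadcasting; whitelists are small (<= a few hundred)
    d = (arr[:, None, :] != arr[None, :, :]).sum(axis=2)
    iu = np.triu_indices(len(entries), k=1)
    return int(d[iu].min())


def generate_whitelist(n: int, length: int, min_distance: int = 3,
                       rng: np.random.Generator | int | None = 0,
                       max_tries: int = 200_000) -> tuple[str, ...]:
    """Rejection-sample ``n`` barcodes of ``length`` nt with pairwise
    Hamming distance >= ``min_distance``.

    Distance >= 3 guarantees that any single substitution corrects
    unambiguously back to its source barcode.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    accepted: list[np.ndarray] = []
    tries = 0
    while len(accepted) < n:
        tries += 1
        if tries > max_tries:
            raise RuntimeError(
                f"could not place {n} barcodes of length {length} at distance "
                f">= {min_distance} in {max_tries} draws")
        cand = rng.integers(0, 4, size=length)
        if all(int((cand != a).sum()) >= min_distance for a in accepted):
            accepted.append(cand)
    lut = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    return tuple(lut[a].tobytes().decode() for a in accepted)


def validate_schema(schema: BarcodeSchema) -> ValidationReport:
    """Check layout constraints; an empty report means the schema is usable."""
    report = ValidationReport()
    for read_len, segments, label in (
        (schema.read1_length, schema.segments_read1, "read1"),
        (schema.read2_length, schema.segments_read2, "read2"),
    ):
        spans = []
        for seg in segments:
            if seg.offset < 0 or seg.length < 1:
                report.violations.append(
                    f"{label}: segment {seg.role} has invalid span "
                    f"(offset {seg.offset}, length {seg.length})")
                continue
            if seg.end > read_len:
                report.violations.append(
                    f"{label}: segment {seg.role} exceeds read length "
                    f"({seg.end} > {read_len})")
            spans.append((seg.offset, seg.end, seg.role))
        spans.sort()
        for (s1, e1, r1), (s2, e2, r2) in zip(spans, spans[1:]):
            if s2 < e1:
                report.violations.append(
                    f"{label}: segments {r1} and {r2} overlap")
    for name, wl, role in (("whitelist_r1", schema.whitelist_r1, ROUND1),
                           ("whitelist_r2", schema.whitelist_r2, ROUND2),
                           ("whitelist_r3", schema.whitelist_r3, ROUND3)):
        if len(set(wl)) != len(wl):
            report.violations.append(f"{name}: duplicate whitelist entry")
        try:
            seg_len = schema.segment(role).length
        except KeyError:
            report.violations.append(f"{name}: no segment with role {role}")
            continue
        for entry in set(wl):
            if len(entry) != seg_len:
                report.violations.append(
                    f"{name}: entry {entry} length {len(entry)} != segment "
                    f"length {seg_len}")
            if set(entry) - set(ALPHABET):
                report.violations.append(
                    f"{name}: entry {entry} contains non-ACGT characters")
    return report


def default_schema(wells: tuple[int, int, int] = (96, 96, 96),
                   well_bc_len: int = 8, linker_len: int = 4,
                   antibody_bc_len: int = 15, umi_len: int = 10,
                   read1_length: int = 100, read2_length: int = 50,
                   whitelist_seed: int = 7) -> BarcodeSchema:
    """Default layout: read 1 = [PCR barcode][linker][round-2][linker][round-1],
    read 2 = [antibody barcode][UMI].

    Ligation appends barcodes to the oligo 3' end, so later rounds sit
    closer to the read-1 start.  Whitelists are rejection-sampled at
    pairwise Hamming >= 3 so single-substitution correction is unambiguous.
    """
    rng = np.random.default_rng(whitelist_seed)
    lk = "".join(ALPHABET[i] for i in rng.integers(0, 4, size=linker_len))
    off = 0
    segs1 = []
    for role in (ROUND3, LINKER, ROUND2, LINKER, ROUND1):
        if role == LINKER:
            segs1.append(Segment(LINKER, off, linker_len, lk))
            off += linker_len
        else:
            segs1.append(Segment(role, off, well_bc_len))
            off += well_bc_len
    if off > read1_length:
        raise ValueError("read 1 too short for the requested segments")
    segs2 = [Segment(ANTIBODY, 0, antibody_bc_len),
             Segment(UMI, antibody_bc_len, umi_len)]
    wl = [generate_whitelist(w, well_bc_len, 3, rng) for w in wells]
    return BarcodeSchema(
        segments_read1=segs1, segments_read2=segs2,
        whitelist_r1=wl[0], whitelist_r2=wl[1], whitelist_r3=wl[2],
        read1_length=read1_length, read2_length=read2_length,
    )


# ---------------------------------------------------------------------------
# antibody panel
# ---------------------------------------------------------------------------

@dataclass
class AntibodyPanel:
    """Named antibodies with their DNA barcodes and class
    (marker / hashtag / isotype_control)."""

    entries: list[tuple[str, str, str]]  # (name, barcode, class)

    def __post_init__(self) -> None:
        seqs = [s for _, s, _ in self.entries]
        if len(set(seqs)) != len(seqs):
            raise ValueError("antibody barcode sequences must be unique")
        names = [n for n, _, _ in self.entries]
        if len(set(names)) != len(names):
            raise ValueError("antibody names must be unique")
        classes = {c for _, _, c in self.entries}
        bad = classes - {MARKER, HASHTAG, ISOTYPE}
        if bad:
            raise ValueError(f"unknown antibody classes: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def names(self) -> list[str]:
        return [n for n, _, _ in self.entries]

    @property
    def barcodes(self) -> tuple[str, ...]:
        return tuple(s for _, s, _ in self.entries)

    def by_class(self, cls: str) -> list[str]:
        return [n for n, _, c in self.entries if c == cls]

    @property
    def markers(self) -> list[str]:
        return self.by_class(MARKER)

    @property
    def hashtags(self) -> list[str]:
        return self.by_class(HASHTAG)

    @property
    def isotypes(self) -> list[str]:
        return self.by_class(ISOTYPE)

    def name_of(self, barcode: str) -> str:
        return {s: n for n, s, _ in self.entries}[barcode]

    def index(self, name: str) -> int:
        return self.names.index(name)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(self.entries, columns=["name", "sequence", "class"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "AntibodyPanel":
        df = pd.read_csv(path, sep="\t")
        return cls(list(df[["name", "sequence", "class"]].itertuples(index=False,
                                                                     name=None)))

    @classmethod
    def from_names(cls, markers: list[str], hashtags: list[str],
                   isotypes: list[str] = ("IgG1-isotype",),
                   barcode_length: int = 15,
                   seed: int = 11) -> "AntibodyPanel":
        """Build a panel with freshly generated barcodes (pairwise distance >= 3)."""
        names = list(markers) + list(hashtags) + list(isotypes)
        bcs = generate_whitelist(len(names), barcode_length, 3,
                                 np.random.default_rng(seed))
        classes = ([MARKER] * len(markers) + [HASHTAG] * len(hashtags)
                   + [ISOTYPE] * len(isotypes))
        return cls(list(zip(names, bcs, classes)))


# ---------------------------------------------------------------------------
# hashtag sample code
# ---------------------------------------------------------------------------

@dataclass
class HashtagCode:
    """Sample multiplexing code: each pooled sample is stained with a
    distinct subset of hashtag antibodies; decoding inverts the map."""

    mapping: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        subsets = list(self.mapping.values())
        if len(set(subsets)) != len(subsets):
            raise ValueError("hashtag subsets must be pairwise distinct")
        self._inverse = {v: k for k, v in self.mapping.items()}

    @property
    def hashtags(self) -> list[str]:
        seen: list[str] = []
        for sub in self.mapping.values():
            for h in sorted(sub):
                if h not in seen:
                    seen.append(h)
        return seen

    def encode(self, sample_id: str) -> frozenset[str]:
        return self.mapping[sample_id]

    def decode(self, subset) -> str | None:
        return self._inverse.get(frozenset(subset))

    def to_tsv(self, path: str | Path) -> None:
        rows = [(s, ",".join(sorted(sub))) for s, sub in self.mapping.items()]
        pd.DataFrame(rows, columns=["sample_id", "hashtags"]).to_csv(
            path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "HashtagCode":
        df = pd.read_csv(path, sep="\t")
        return cls({r.sample_id: frozenset(r.hashtags.split(","))
                    for r in df.itertuples()})


def build_hashtag_code(sample_ids: list[str],
                       hashtag_names: list[str]) -> HashtagCode:
    """Assign each sample a distinct subset of hashtags.

    Deterministic order: singletons in hashtag order, then pairs, triples,
    ... in lexicographic order of hashtag indices.  With four hashtags this
    yields 15 usable codes (the empty set is unusable).
    """
    k = len(hashtag_names)
    capacity = 2 ** k - 1
    if len(sample_ids) > capacity:
        raise ValueError(
            f"{len(sample_ids)} samples exceed the {capacity} non-empty "
            f"subsets of {k} hashtags")
    subsets = []
    for size in range(1, k + 1):
        for combo in itertools.combinations(range(k), size):
            subsets.append(frozenset(hashtag_names[i] for i in combo))
    return HashtagCode(dict(zip(sample_ids, subsets)))
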