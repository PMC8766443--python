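"""Demultiplexer: parsing, barcode correction, UMI collapse, cell calling."""

import itertools
from collections import Counter

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import qbc2 as q
from qbc2.demux import LEDGER_KEYS, ReadTooShortError
from qbc2.simulate import umi_to_str


class TestParseReadPair:
    def test_parsing_inverts_construction(self, default_schema):
        s = default_schema
        r1 = list("A" * s.read1_length)
        parts = {"round1_well": s.whitelist_r1[3],
                 "round2_well": s.whitelist_r2[7],
                 "round3_pcr": s.whitelist_r3[1]}
        for role, val in parts.items():
            seg = s.segment(role)
            r1[seg.offset:seg.end] = val
        ab, umi = "G" * 15, "T" * 10
        rec = q.parse_read_pair("".join(r1), ab + umi + "A" * 25, s, name="r")
        assert (rec.r1_bc, rec.r2_bc, rec.r3_bc) == (
            parts["round1_well"], parts["round2_well"], parts["round3_pcr"])
        assert rec.antibody == ab and rec.umi == umi

    def test_truncated_read_is_rejected(self, default_schema):
        # read 1 ends inside the round-1 barcode segment
        with pytest.raises(ReadTooShortError, match="truncated"):
            q.parse_read_pair("A" * 30, "A" * 50, default_schema)
        with pytest.raises(ReadTooShortError, match="truncated"):
            q.parse_read_pair("A" * 100, "A" * 20, default_schema)

    def test_noiseless_reads_parse_on_whitelist(self, noiseless_run):
        import gzip
        r = noiseless_run
        s = r["schema"]
        with gzip.open(r["sim"].r1_fastq, "rt") as f1, \
                gzip.open(r["sim"].r2_fastq, "rt") as f2:
            for _ in range(200):
                f1.readline()
                s1 = f1.readline().strip()
                f1.readline(), f1.readline()
                f2.readline()
                s2 = f2.readline().strip()
                f2.readline(), f2.readline()
                if not s1:
                    break
                rec = q.parse_read_pair(s1, s2, s)
                assert rec.r1_bc in s.whitelist_r1
                assert rec.r2_bc in s.whitelist_r2
                assert rec.r3_bc in s.whitelist_r3
                assert rec.antibody in r["config"].panel.barcodes


class TestCorrectBarcode:
    def test_single_mismatch_corrects(self):
        assert q.correct_barcode("AAAT", ["AAAA", "TTTT"], 1) == "AAAA"

    def test_out_of_radius_rejects(self):
        assert q.correct_barcode("AATT", ["AAAA", "TTTT"], 1) is None

    def test_ambiguous_tie_rejects(self):
        assert q.correct_barcode("AT", ["AA", "TT"], 1) is None

    def test_length_mismatch_is_an_error(self):
        with pytest.raises(ValueError):
            q.correct_barcode("AAA", ["AAAA"], 1)

    def test_n_base_counts_as_mismatch(self):
        assert q.correct_barcode("AAAN", ["AAAA", "TTTT"], 1) == "AAAA"
        assert q.correct_barcode("AANN", ["AAAA", "TTTT"], 1) is None

    def test_every_single_substitution_corrects_back(self, small_whitelist):
        # exhaustive: distance >= 3 whitelists are radius-1 perfect codes
        for entry in small_whitelist:
            for pos, base in itertools.product(range(len(entry)), "ACGT"):
                if entry[pos] == base:
                    continue
                corrupted = entry[:pos] + base + entry[pos + 1:]
                assert q.correct_barcode(corrupted, small_whitelist, 1) == entry


class TestCollapseUmis:
    def test_directional_absorbs_satellite(self):
        assert q.collapse_umis(Counter({"AAAA": 5, "AAAT": 1}),
                               "directional", 1) == 1

    def test_exact_counts_distinct_strings(self):
        assert q.collapse_umis(Counter({"AAAA": 5, "AAAT": 1}), "exact") == 2

    def test_empty_set_is_zero(self):
        assert q.collapse_umis([], "directional") == 0
        assert q.collapse_umis([], "exact") == 0

    def test_directional_respects_count_rule(self):
        # counts 2 vs 2: 2 >= 2*2-1 is false, no merge
        assert q.collapse_umis(Counter({"AAAA": 2, "AAAT": 2}),
                               "directional", 1) == 2

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.integers(min_value=0, max_value=255), min_size=1,
                    max_size=25))
    def test_collapse_monotonicity(self, codes):
        umis = list(umi_to_str(np.array(codes), 4))
        raw = len(umis)
        exact = q.collapse_umis(umis, "exact")
        directional = q.collapse_umis(umis, "directional", 1)
        assert directional <= exact <= raw
        assert directional >= 1


class TestCallCells:
    def _rec(self, triple, ab="CD4", umi="AAAA", name="r"):
        return q.RawRecord(name, *triple, ab, umi)

    def test_records_sharing_a_triple_become_one_cell(self):
        triple = ("AAAA", "CCCC", "GGGG")
        recs = [self._rec(triple, umi=u) for u in ("AAAA", "CCCC", "GGGG")]
        cells, ledger = q.call_cells(recs, min_umi=1)
        assert len(cells) == 1
        assert cells[0].raw_reads() == 3
        assert cells[0].collapsed_counts("exact") == {"CD4": 3}
        assert ledger["assigned"] == 3

    def test_rejected_fields_go_to_the_ledger(self):
        recs = [self._rec(("AAAA", "CCCC", "GGGG")),
                q.RawRecord("r", None, "CCCC", "GGGG", "CD4", "AAAA"),
                q.RawRecord("r", "AAAA", "CCCC", "GGGG", None, "AAAA")]
        _, ledger = q.call_cells(recs, min_umi=1)
        assert ledger["round1_barcode"] == 1
        assert ledger["antibody_barcode"] == 1
        assert ledger["assigned"] == 1

    def test_min_umi_filter_drops_small_cells(self):
        triple_a = ("AAAA", "CCCC", "GGGG")
        triple_b = ("TTTT", "CCCC", "GGGG")
        # doubled dinucleotides: pairwise Hamming >= 2, no directional merges
        umis = [a * 2 + b * 2 for a, b in itertools.product("ACGT", "ACGT")]
        recs = [self._rec(triple_a, umi=u) for u in umis[:12]]
        recs += [self._rec(triple_b)]
        cells, ledger = q.call_cells(recs, min_umi=5)
        assert [c.triple for c in cells] == [triple_a]
        assert ledger["low_umi_cell"] == 1


class TestRoundTrip:
    def test_noiseless_demux_equals_truth_regroup(self, noiseless_run,
                                                  noiseless_counts):
        """Brute-force oracle: regroup the truth molecule table by well
        triple and count distinct UMIs; demux must match exactly."""
        r = noiseless_run
        cm, _ = noiseless_counts
        schema = r["schema"]
        mol = pd.read_csv(r["sim"].molecules_tsv, sep="\t")
        seq = mol[mol["sequenced"]]
        wl = [schema.whitelist_r1, schema.whitelist_r2, schema.whitelist_r3]
        keys = ["-".join(w[i] for w, i in zip(
            wl, (row.r1_well, row.r2_well, row.r3_well)))
            for row in seq.itertuples()]
        oracle = (seq.assign(key=keys)
                  .groupby(["key", "antibody"], observed=True)["umi_seq"]
                  .nunique())
        observed = cm.to_frame()
        assert set(oracle.index.get_level_values("key")) == set(cm.barcodes)
        for (key, ab), n in oracle.items():
            assert observed.at[key, ab] == n
        assert int(observed.to_numpy().sum()) == int(oracle.sum())

    def test_ledger_conserves_reads(self, noiseless_run, noiseless_counts):
        _, ledger = noiseless_counts
        parts = sum(ledger[k] for k in LEDGER_KEYS if k != "input_pairs")
        assert parts == ledger["input_pairs"] == noiseless_run["sim"].n_reads

    def test_ht3_late_spikes_are_never_called(self, noiseless_run,
                                              noiseless_counts):
        cm, _ = noiseless_counts
        ht3_idx = cm.antibody_names.index("HT3")
        dense = cm.matrix.toarray()
        dominant_ht3 = dense[:, ht3_idx] > dense.sum(axis=1) * 0.5
        assert dominant_ht3.sum() == 0


class TestCountMatrixIO:
    def _cm(self, mat, barcodes, names):
        import scipy.sparse as sp
        features = pd.DataFrame({"name": names,
                                 "class": ["marker"] * len(names)})
        return q.CountMatrix(sp.csr_matrix(np.array(mat)), barcodes, features)

    def test_two_by_two_roundtrip(self, tmp_path):
        cm = self._cm([[1, 0], [0, 3]], ["b1", "b2"], ["CD4", "CD8"])
        q.write_count_matrix(cm, tmp_path)
        mtx_text = (tmp_path / "matrix.mtx").read_text()
        assert "2 2 2" in mtx_text  # two nonzeros
        back = q.read_count_matrix(tmp_path)
        assert (back.matrix.toarray() == cm.matrix.toarray()).all()
        assert back.barcodes == cm.barcodes
        assert list(back.features["name"]) == ["CD4", "CD8"]

    def test_empty_matrix_roundtrip(self, tmp_path):
        cm = self._cm(np.zeros((0, 2)), [], ["CD4", "CD8"])
        q.write_count_matrix(cm, tmp_path)
        back = q.read_count_matrix(tmp_path)
        assert back.matrix.shape == (0, 2)
        assert back.barcodes == []

    def test_demuxed_matrix_roundtrips(self, tmp_path, noiseless_counts):
        cm, _ = noiseless_counts
        q.write_count_matrix(cm, tmp_path)
        back = q.read_count_matrix(tmp_path)
        assert (back.matrix != cm.matrix).nnz == 0
        assert back.barcodes == cm.barcodes
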