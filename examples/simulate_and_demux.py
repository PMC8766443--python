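"""Simulate a small mixed-cell-line experiment and demultiplex it.

Two cell lines (Jurkat-like and HEK293T-like) are mixed 1:1, stained with a
7-antibody panel plus hashtags, run through two ligation rounds and one PCR
round, sequenced with substitution errors, and then reconstructed from the
FASTQ alone.  Spike-in controls audit the chemistry: HT2 cells (hashtag
only, present from the start) measure antibody swapping; HT3 cells (added
after round 1) measure splint-blocking failure and must never be called.
"""

import tempfile
from pathlib import Path

import qbc2 as q

with tempfile.TemporaryDirectory() as tmp:
    schema, cfg = q.fixture_config("two_lines", seed=1, n_cells=600)
    cells, molecules, sim_out = q.run_simulation(schema, cfg, Path(tmp))
    print(f"simulated {len(cells)} cells -> {len(molecules):,} antibody "
          f"molecules -> {sim_out.n_reads:,} read pairs")

    counts, ledger = q.demux_fastq(sim_out.r1_fastq, sim_out.r2_fastq,
                                   schema, cfg.panel)
    print(f"called {len(counts.barcodes)} cells; reads assigned: "
          f"{ledger['assigned']:,} / {ledger['input_pairs']:,}")
    rejected = {k: v for k, v in ledger.items()
                if k not in ("input_pairs", "assigned") and v}
    print(f"rejected reads by reason: {rejected}")

    clr = q.clr_transform(counts)
    qc = q.control_qc(counts, cfg.panel, clr=clr, ledger=ledger)
    print(f"HT2 controls recovered: {qc.ht2_cells_detected} "
          f"({qc.ht2_fraction:.1%} of called cells; generated at 5% of the "
          f"cell pool)")
    print(f"HT3 late-spike cells called: {qc.ht3_cells_detected} "
          f"(must be 0 when blocking is perfect)")
    print(f"marker signal on HT2 controls vs ordinary cells (mean CLR): "
          f"{qc.ht2_marker_clr_mean:.2f} vs {qc.other_marker_clr_mean:.2f}")
    print()
    print("Meaning: the demultiplexer reconstructs the loaded cells from")
    print("reads alone, the HT2 fraction matches its spike-in rate, and")
    print("control cells show only background marker signal (no swapping).")
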