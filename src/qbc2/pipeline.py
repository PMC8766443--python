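"""End-to-end pipeline: simulate -> demux -> quantify -> analyze.

Also defines the named study fixtures:

* ``two_lines``     — two cell lines mixed 1:1 and stained with a 7-antibody
                      panel (CD56, CD155, CD29, CD4, CD45, CD28, isotype),
                      plus 5% hashtag-only spike-in controls added before
                      round 1 (HT2) and after round 1 (HT3), plus a small
                      non-specifically stained population.
* ``ten_patients``  — ten pooled samples coded by combinations of four
                      hashtag antibodies, 29-antibody panel, mixed blood
                      cell types including clonal (CLL-like and ATLL-like)
                      populations.
* ``controls_only`` — spike-in control populations alone.
"""

from __future__ import annotations

import dataclasses
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import kmeans_cluster, pca, tsne_embed
from .demux import demux_fastq, write_count_matrix, write_ledger
from .quantify import assign_samples, clr_transform, control_qc
from .schema import (AntibodyPanel, BarcodeSchema, HashtagCode,
                     build_hashtag_code, default_schema)
from .simulate import CellType, SimConfig, run_simulation

FIXTURE_NAMES = ("two_lines", "ten_patients", "controls_only")


# ---------------------------------------------------------------------------
# named fixtures
# ---------------------------------------------------------------------------

def _two_lines_panel() -> AntibodyPanel:
    return AntibodyPanel.from_names(
        markers=["CD56", "CD155", "CD29", "CD4", "CD45", "CD28"],
        hashtags=["HT1", "HT2", "HT3"], isotypes=["IgG1-isotype"], seed=11)


def _two_lines_config(seed: int, n_cells: int = 2000) -> SimConfig:
    panel = _two_lines_panel()
    iso = "IgG1-isotype"
    cell_types = {
        "jurkat": CellType("jurkat", {
            "CD4": 60, "CD45": 50, "CD28": 35, "CD29": 12,
            "CD56": 0.4, "CD155": 0.4, iso: 1.0}),
        "hek293t": CellType("hek293t", {
            "CD56": 60, "CD155": 50, "CD29": 45,
            "CD4": 0.4, "CD45": 0.4, "CD28": 0.4, iso: 1.0}),
        # non-specific staining: uniform dim markers, bright isotype, stray HT3
        "nonspecific": CellType("nonspecific", {
            "CD56": 8, "CD155": 8, "CD29": 8, "CD4": 8, "CD45": 8,
            "CD28": 8, iso: 45, "HT3": 25}),
    }
    return SimConfig(
        panel=panel, cell_types=cell_types,
        sample_sizes={"mix": n_cells},
        sample_composition={"mix": {"jurkat": 0.475, "hek293t": 0.475,
                                    "nonspecific": 0.05}},
        hashtag_code=HashtagCode({"mix": frozenset({"HT1"})}),
        ht2_spike_fraction=0.05, ht3_spike_fraction=0.05,
        mean_reads_per_molecule=1.2, error_rate=0.005, seed=seed)


def _ten_patients_config(seed: int, cells_per_sample: int = 150) -> SimConfig:
    markers = ["CD45", "CD3", "CD4", "CD8", "CD19", "CD20", "CD56", "CD14",
               "CD16", "CD25", "PD1", "CTLA4", "kappa", "lambda", "CD5",
               "CD10", "CD23", "CD38", "HLA-DR", "CD7", "CD2", "CD30"]
    panel = AntibodyPanel.from_names(
        markers=markers, hashtags=["H1", "H2", "H3", "H4", "HT2", "HT3"],
        isotypes=["IgG1-isotype"], seed=13)
    base = {"CD45": 50.0}
    types = {
        "t_cd4": {**base, "CD3": 45, "CD4": 40, "CD2": 30, "CD7": 25, "CD5": 18},
        "t_cd8": {**base, "CD3": 45, "CD8": 40, "CD2": 30, "CD7": 25},
        "b_kappa": {**base, "CD19": 45, "CD20": 40, "kappa": 35,
                    "HLA-DR": 30},
        "b_lambda": {**base, "CD19": 45, "CD20": 40, "lambda": 35,
                     "HLA-DR": 30},
        "nk": {**base, "CD56": 40, "CD16": 35, "CD7": 25, "CD2": 20},
        "mono": {"CD45": 45, "CD14": 45, "CD16": 15, "HLA-DR": 35},
        # clonal populations driving the clinical-style readouts
        "cll_kappa": {"CD45": 40, "CD19": 45, "CD5": 35, "CD23": 30,
                      "CD20": 10, "kappa": 35, "HLA-DR": 30},
        "atll": {**base, "CD3": 45, "CD4": 40, "CD25": 45, "PD1": 35,
                 "CTLA4": 15, "CD7": 4},
    }
    cell_types = {n: CellType(n, m) for n, m in types.items()}
    normal = {"t_cd4": 0.35, "t_cd8": 0.2, "b_kappa": 0.1, "b_lambda": 0.08,
              "nk": 0.12, "mono": 0.15}
    composition = {f"p{i}": dict(normal) for i in range(1, 11)}
    composition["p1"] = {"cll_kappa": 0.55, "t_cd4": 0.2, "t_cd8": 0.1,
                         "nk": 0.05, "mono": 0.1}
    composition["p9"] = {"atll": 0.5, "t_cd4": 0.15, "t_cd8": 0.1,
                         "b_kappa": 0.05, "b_lambda": 0.05, "nk": 0.05,
                         "mono": 0.1}
    samples = list(composition)
    return SimConfig(
        panel=panel, cell_types=cell_types,
        sample_sizes={s: cells_per_sample for s in samples},
        sample_composition=composition,
        hashtag_code=build_hashtag_code(samples, ["H1", "H2", "H3", "H4"]),
        ht2_spike_fraction=0.05, ht3_spike_fraction=0.05,
        mean_reads_per_molecule=1.2, error_rate=0.005, seed=seed)


def _controls_only_config(seed: int, n_controls: int = 300) -> SimConfig:
    cfg = _two_lines_config(seed, n_cells=0)
    return dataclasses.replace(cfg, ht2_spike_n=n_controls,
                               ht3_spike_n=n_controls)


def fixture_config(name: str, seed: int,
                   **overrides) -> tuple[BarcodeSchema, SimConfig]:
    """Schema + simulation config for a named study scenario.

    Size arguments (``n_cells``, ``cells_per_sample``, ``n_controls``) go to
    the scenario factory; any remaining keyword naming a SimConfig field
    overrides that field.
    """
    size_keys = {"two_lines": "n_cells", "ten_patients": "cells_per_sample",
                 "controls_only": "n_controls"}
    if name not in size_keys:
        raise ValueError(f"unknown fixture {name!r}; choose from "
                         f"{FIXTURE_NAMES}")
    factory = {"two_lines": _two_lines_config,
               "ten_patients": _ten_patients_config,
               "controls_only": _controls_only_config}[name]
    kwargs = {}
    if size_keys[name] in overrides:
        kwargs[size_keys[name]] = overrides.pop(size_keys[name])
    config = factory(seed, **kwargs)
    sim_fields = {f.name for f in dataclasses.fields(SimConfig)}
    unknown = set(overrides) - sim_fields
    if unknown:
        raise ValueError(f"unknown overrides: {sorted(unknown)}")
    if overrides:
        config = dataclasses.replace(config, **overrides)
    return default_schema(), config


def make_fixture(name: str, seed: int, out_dir: str | Path,
                 **overrides) -> Path:
    """Write a complete named fixture: schema, panel, code, FASTQ, truth."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    schema, config = fixture_config(name, seed, **overrides)
    schema.save(out / "schema")
    config.panel.to_tsv(out / "panel.tsv")
    config.hashtag_code.to_tsv(out / "hashtag_code.tsv")
    run_simulation(schema, config, out)
    (out / "fixture.yaml").write_text(yaml.safe_dump(
        {"fixture": name, "seed": seed,
         "overrides": {k: v for k, v in overrides.items()}}))
    return out


# ---------------------------------------------------------------------------
# run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Serializable description of one pipeline run."""

    seed: int = 0
    fixture: str = "two_lines"
    sim: dict = field(default_factory=dict)        # fixture size + SimConfig overrides
    demux: dict = field(default_factory=dict)      # min_umi, collapse, umi_mismatch
    quantify: dict = field(default_factory=dict)   # pseudocount, log_base
    analysis: dict = field(default_factory=dict)   # k, n_components, perplexity, run_tsne

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if path.suffix == ".toml":
            doc = tomllib.loads(path.read_text())
        else:
            doc = yaml.safe_load(path.read_text())
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**doc)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))


ALL_STAGES = ("simulate", "demux", "quantify", "analyze")


def run_pipeline(config: RunConfig, out_dir: str | Path,
                 stages=ALL_STAGES) -> dict:
    """Execute the requested stages in order, writing artifacts and a
    line-structured log (stage, metric, value) under ``out_dir``.

    Later stages read earlier stages' on-disk artifacts, so a partial run
    (e.g. ``stages=("demux", "quantify")``) over a pre-simulated directory
    produces identical outputs to a full run with the same seed.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = tuple(stages)
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    log: list[tuple[str, str, object]] = []
    schema, sim_config = fixture_config(config.fixture, config.seed,
                                        **config.sim)
    panel = sim_config.panel
    results: dict = {"schema": schema, "sim_config": sim_config}
    sim_dir = out / "sim"

    if "simulate" in stages:
        cells, molecules, sim_out = run_simulation(schema, sim_config, sim_dir)
        panel.to_tsv(sim_dir / "panel.tsv")
        sim_config.hashtag_code.to_tsv(sim_dir / "hashtag_code.tsv")
        schema.save(sim_dir / "schema")
        results.update(cells=cells, molecules=molecules, sim_output=sim_out)
        log += [("simulate", "n_cells", len(cells)),
                ("simulate", "n_molecules", len(molecules)),
                ("simulate", "n_read_pairs", sim_out.n_reads)]

    if "demux" in stages:
        r1, r2 = sim_dir / "reads_R1.fastq.gz", sim_dir / "reads_R2.fastq.gz"
        if not r1.exists():
            raise FileNotFoundError(f"demux stage needs {r1}; run simulate "
                                    f"first or point out_dir at an existing run")
        counts, ledger = demux_fastq(r1, r2, schema, panel,
                                     **config.demux)
        demux_dir = out / "demux"
        write_count_matrix(counts, demux_dir / "counts")
        write_ledger(ledger, demux_dir / "discard_ledger.tsv")
        results.update(counts=counts, ledger=ledger)
        log += [("demux", "n_called_cells", len(counts.barcodes)),
                *((f"demux", f"reads_{k}", v) for k, v in ledger.items())]

    if "quantify" in stages:
        counts = results.get("counts")
        if counts is None:
            from .demux import read_count_matrix
            counts = read_count_matrix(out / "demux" / "counts")
        clr = clr_transform(counts, **config.quantify)
        qdir = out / "quantify"
        qdir.mkdir(parents=True, exist_ok=True)
        clr.save(qdir / "clr.tsv")
        assignment = assign_samples(clr, sim_config.hashtag_code)
        assignment.save(qdir / "assignment.tsv", barcodes=counts.barcodes)
        qc = control_qc(counts, panel, clr=clr,
                        ht2_hashtag=sim_config.ht2_hashtag,
                        ht3_hashtag=sim_config.ht3_hashtag,
                        ledger=results.get("ledger"))
        qc.save(qdir / "qc_report.tsv")
        results.update(clr=clr, assignment=assignment, qc=qc)
        log += [("quantify", "ht2_cells_detected", qc.ht2_cells_detected),
                ("quantify", "ht3_cells_detected", qc.ht3_cells_detected),
                ("quantify", "n_undetermined",
                 assignment.labels.count("undetermined"))]

    if "analyze" in stages:
        clr = results.get("clr")
        if clr is None:
            raise FileNotFoundError("analyze stage needs the quantify stage")
        n_comp = config.analysis.get("n_components", 3)
        k = config.analysis.get("k", 4)
        emb = pca(clr, n_components=min(n_comp, clr.values.shape[1]))
        labels = kmeans_cluster(emb.coords, k=k, seed=config.seed)
        adir = out / "analysis"
        adir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(emb.coords, index=clr.barcodes,
                     columns=[f"PC{i+1}" for i in range(emb.n_components)]
                     ).rename_axis("barcode").to_csv(adir / "pca.tsv", sep="\t")
        pd.DataFrame({"barcode": clr.barcodes, "cluster": labels}).to_csv(
            adir / "clusters.tsv", sep="\t", index=False)
        results.update(pca=emb, clusters=labels)
        if config.analysis.get("run_tsne", False):
            ts = tsne_embed(clr, seed=config.seed,
                            perplexity=config.analysis.get("perplexity", 30.0))
            pd.DataFrame(ts.coords, index=clr.barcodes,
                         columns=["TSNE1", "TSNE2"]).rename_axis(
                "barcode").to_csv(adir / "tsne.tsv", sep="\t")
            results["tsne"] = ts
        log += [("analyze", "k", k), ("analyze", "n_components", n_comp)]

    config.save(out / "resolved_config.yaml")
    pd.DataFrame(log, columns=["stage", "metric", "value"]).to_csv(
        out / "run_log.tsv", sep="\t", index=False)
    results["log"] = log
    return results


def truth_flags_by_triple(cells_tsv: str | Path) -> dict[str, str]:
    """Map called-barcode triple keys to simulation control flags."""
    df = pd.read_csv(cells_tsv, sep="\t")
    return {t: f for t, f in zip(df["triple"], df["control_flag"])
            if "*" not in t}
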