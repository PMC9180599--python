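"""Config-driven pipeline: simulate -> DE -> RRA -> validate -> cobind ->
enrich -> annotate -> profile, with per-stage logs and a JSON manifest.

The pipeline exists so the whole analysis can be rerun from one YAML file;
each stage is a thin wrapper over the library modules. A single global
seed derives independent per-stage seeds, so toggling one stage never
perturbs another's random stream.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import annotation, diffexpr, motifs, perm_enrich, rra, signal_profile, simdata
from .intervals import (
    PeakSet,
    classify_cobinding,
    read_bed,
    read_chrom_sizes,
    write_bed,
    write_chrom_sizes,
)
from .simdata import SimConfig, derive_seed

logger = logging.getLogger(__name__)

STAGES = ["simulate", "de", "rra", "validate", "cobind", "enrich", "annotate", "profile"]


@dataclass
class PipelineConfig:
    out_dir: Path
    seed: int = 0
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    sim: dict[str, Any] = field(default_factory=dict)
    de: dict[str, Any] = field(default_factory=dict)
    rra: dict[str, Any] = field(default_factory=dict)
    enrich: dict[str, Any] = field(default_factory=dict)
    profile: dict[str, Any] = field(default_factory=dict)
    inputs: dict[str, str] = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None,
                  out_dir: str | None = None) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {"out_dir", "seed", "stages", "sim", "de", "rra",
                              "enrich", "profile", "inputs"}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        bad_stages = set(raw.get("stages", [])) - set(STAGES)
        if bad_stages:
            raise ValueError(f"unknown stages: {sorted(bad_stages)}")
        cfg = cls(
            out_dir=Path(out_dir or raw.get("out_dir", "myorra_out")),
            seed=int(seed if seed is not None else raw.get("seed", 0)),
            stages=list(raw.get("stages", STAGES)),
            sim=dict(raw.get("sim", {})),
            de=dict(raw.get("de", {})),
            rra=dict(raw.get("rra", {})),
            enrich=dict(raw.get("enrich", {})),
            profile=dict(raw.get("profile", {})),
            inputs={k: str(v) for k, v in (raw.get("inputs") or {}).items()},
        )
        for key, p in cfg.inputs.items():
            if not Path(p).exists():
                raise FileNotFoundError(f"configured input {key!r} not found: {p}")
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the enabled stages in dependency order; return the manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {"seed": config.seed, "stages": {}}
    state: dict[str, Any] = {}

    def record(stage: str, params: dict, outputs: list[Path]) -> None:
        manifest["stages"][stage] = {
            "parameters": params,
            "outputs": {str(p.relative_to(out)): _sha256(p) for p in outputs},
        }

    try:
        for stage in STAGES:
            if stage not in config.stages:
                continue
            fn = _STAGE_FUNCS[stage]
            params, outputs = fn(config, out, state)
            record(stage, params, outputs)
    except Exception as exc:  # partial manifest with the failure recorded
        manifest["failed"] = {"stage": stage, "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


# ---------------------------------------------------------------------------
# Stage implementations


def _stage_simulate(config: PipelineConfig, out: Path, state: dict):
    sim_cfg = SimConfig(seed=derive_seed(config.seed, "simulate"), **config.sim)
    chrom_sizes, genes = simdata.simulate_genome(sim_cfg)
    datasets, truth = simdata.simulate_count_datasets(genes, sim_cfg)

    write_chrom_sizes(chrom_sizes, out / "chrom.sizes")
    genes.to_csv(out / "genes.tsv", sep="\t", index=False)
    outputs = [out / "chrom.sizes", out / "genes.tsv"]
    for i, (counts, groups) in enumerate(datasets, start=1):
        p = out / f"counts_ds{i}.tsv"
        counts.to_csv(p, sep="\t")
        outputs.append(p)
    pd.DataFrame({"gene": sorted(truth.true_up)}).to_csv(out / "truth_up.tsv", sep="\t", index=False)
    pd.DataFrame({"gene": sorted(truth.true_down)}).to_csv(out / "truth_down.tsv", sep="\t", index=False)
    outputs += [out / "truth_up.tsv", out / "truth_down.tsv"]

    design = {("tfB", "tfA"): 0.8}
    peaksets, peak_truth = simdata.simulate_peaksets(
        chrom_sizes, design, sim_cfg, n_peaks=500,
        annotations={"se_like": ("tfA", 800, 8000)},
    )
    for name, ps in peaksets.items():
        p = out / f"{name}.bed"
        write_bed(ps, p)
        outputs.append(p)

    pwm = motifs.build_pwm(_demo_pwm_counts(), name="demo_motif")
    motifs.write_pwm(pwm, out / "motif.pwm")
    seqs, embedded = simdata.simulate_sequences(
        peaksets["tfA"], pwm, sim_cfg.motif_embed_rate, sim_cfg
    )
    simdata.write_fasta(seqs, out / "peaks.fa")
    outputs += [out / "motif.pwm", out / "peaks.fa"]

    up_anchors = [(r.chrom, int(r.tss)) for r in
                  genes[genes["gene"].isin(truth.true_up)].itertuples(index=False)]
    down_anchors = [(r.chrom, int(r.tss)) for r in
                    genes[genes["gene"].isin(truth.true_down)].itertuples(index=False)]
    track_df = simdata.simulate_coverage(up_anchors, down_anchors, sim_cfg, factor=3.0,
                                         chrom_sizes=chrom_sizes)
    signal_profile.write_track(track_df, out / "coverage.bedgraph")
    outputs.append(out / "coverage.bedgraph")

    terms = simdata.simulate_term_map(genes, truth, sim_cfg)
    with open(out / "term2gene.tsv", "w") as fh:
        for term, tg in terms.items():
            for g in sorted(tg):
                fh.write(f"{term}\t{g}\n")
    edges = simdata.simulate_ppi_edges(genes["gene"].tolist()[:300], sim_cfg)
    edges.to_csv(out / "ppi_edges.tsv", sep="\t", index=False, header=False)
    outputs += [out / "term2gene.tsv", out / "ppi_edges.tsv"]

    state.update(
        chrom_sizes=chrom_sizes, genes=genes, datasets=datasets, truth=truth,
        peaksets=peaksets, pwm=pwm, seqs=seqs, track_df=track_df, terms=terms,
        edges=edges,
    )
    return ({"sim": {**config.sim, "seed": sim_cfg.seed}}, outputs)


def _require(state: dict, key: str, config: PipelineConfig, loader=None):
    if key in state:
        return state[key]
    if loader is not None:
        value = loader(config)
        state[key] = value
        return value
    raise RuntimeError(f"stage requires {key!r}; run the simulate stage or provide inputs")


def _stage_de(config: PipelineConfig, out: Path, state: dict):
    datasets = _require(state, "datasets", config, _load_datasets)
    tables = []
    outputs = []
    for i, (counts, groups) in enumerate(datasets, start=1):
        table = diffexpr.differential_test(counts, groups, **config.de)
        p = out / f"degs_ds{i}.tsv"
        diffexpr.write_deg_table(table, p)
        tables.append(table)
        outputs.append(p)
    state["deg_tables"] = tables
    return (config.de, outputs)


def _load_datasets(config: PipelineConfig):
    datasets = []
    i = 1
    while True:
        key = f"counts_ds{i}"
        if key not in config.inputs:
            break
        counts = diffexpr.read_counts(config.inputs[key])
        groups = [c.split("_")[0] for c in counts.columns]
        datasets.append((counts, groups))
        i += 1
    if not datasets:
        raise RuntimeError("no count matrices available (inputs counts_ds1..)")
    return datasets


def _stage_rra(config: PipelineConfig, out: Path, state: dict):
    def _load_tables(c: PipelineConfig):
        tables = [diffexpr.read_deg_table(p) for k, p in sorted(c.inputs.items())
                  if k.startswith("degs_ds")]
        if not tables:
            raise RuntimeError("no DEG tables available (inputs degs_ds1..)")
        return tables

    tables = _require(state, "deg_tables", config, _load_tables)
    params = {"padj_max": 0.01, "abs_log2fc_min": 1.0, **config.rra}
    universe = sorted(set().union(*(set(t["gene"]) for t in tables)))
    outputs = []
    robust = {}
    for direction in ("up", "down"):
        lists = [
            rra.RankedGeneList.from_deg_table(t, f"ds{i + 1}", direction=direction)
            for i, t in enumerate(tables)
        ]
        res = rra.aggregate_lists(lists, universe, direction=direction, **params)
        p = out / f"robust_{direction}.tsv"
        res.to_csv(p, sep="\t", index=False)
        outputs.append(p)
        robust[direction] = res
    state["robust"] = robust
    return (params, outputs)


def _stage_validate(config: PipelineConfig, out: Path, state: dict):
    robust = _require(state, "robust", config)
    truth = state.get("truth")
    report: dict[str, Any] = {}
    if truth is not None:
        called_up = set(robust["up"].loc[robust["up"]["robust"], "gene"])
        called_down = set(robust["down"].loc[robust["down"]["robust"], "gene"])
        if called_up:
            report["up"] = rra.overlap_report(called_up, truth.true_up)
        if called_down:
            report["down"] = rra.overlap_report(called_down, truth.true_down)
    p = out / "validation.json"
    p.write_text(json.dumps(report, indent=2))
    return ({}, [p])


def _stage_cobind(config: PipelineConfig, out: Path, state: dict):
    peaksets = _require(state, "peaksets", config, _load_peaksets)
    a, b = peaksets["tfA"], peaksets["tfB"]
    classes = classify_cobinding(a, b)
    outputs = []
    for label, ps in classes.items():
        p = out / f"cobind_{label.replace('+', 'p').replace('-', 'm')}.bed"
        write_bed(ps, p)
        outputs.append(p)
    summary = {label: len(ps) for label, ps in classes.items()}
    p = out / "cobind_summary.json"
    p.write_text(json.dumps(summary, indent=2))
    outputs.append(p)
    state["cobind_classes"] = classes
    return ({}, outputs)


def _load_peaksets(config: PipelineConfig):
    sets = {}
    for key, path in config.inputs.items():
        if key.startswith("peaks_"):
            sets[key.removeprefix("peaks_")] = read_bed(path, name=key.removeprefix("peaks_"))
    if not sets:
        raise RuntimeError("no peak sets available (inputs peaks_<name>)")
    return sets


def _stage_enrich(config: PipelineConfig, out: Path, state: dict):
    peaksets = _require(state, "peaksets", config, _load_peaksets)
    chrom_sizes = _require(
        state, "chrom_sizes", config,
        lambda c: read_chrom_sizes(c.inputs["chrom_sizes"]),
    )
    params = {"n_perm": 1000, **config.enrich}
    res = perm_enrich.fold_enrichment(
        target=peaksets["tfA"],
        annotation=peaksets["se_like"],
        chrom_sizes=chrom_sizes,
        seed=derive_seed(config.seed, "enrich"),
        **params,
    )
    p = out / "enrichment.tsv"
    res.to_frame().to_csv(p, sep="\t", index=False)
    state["enrichment"] = res
    return (params, [p])


def _stage_annotate(config: PipelineConfig, out: Path, state: dict):
    genes = _require(state, "genes", config,
                     lambda c: annotation.read_gene_table(c.inputs["genes"]))
    chrom_sizes = _require(state, "chrom_sizes", config,
                           lambda c: read_chrom_sizes(c.inputs["chrom_sizes"]))
    peaksets = _require(state, "peaksets", config, _load_peaksets)
    terms = _require(state, "terms", config,
                     lambda c: annotation.read_term2genes(c.inputs["term2gene"]))
    domains = annotation.extend_domains(
        annotation.basal_domains(genes, chrom_sizes=chrom_sizes),
        chrom_sizes=chrom_sizes,
    )
    gene2sites, _ = annotation.associate_regions(peaksets["tfA"], domains)
    associated = sorted(g for g, s in gene2sites.items() if s)
    universe = sorted(set().union(*terms.values()))
    enr = annotation.hypergeom_enrich(associated, universe, terms)
    outputs = []
    p = out / "associated_genes.tsv"
    pd.DataFrame({"gene": associated}).to_csv(p, sep="\t", index=False)
    outputs.append(p)
    p = out / "term_enrichment.tsv"
    enr.to_csv(p, sep="\t", index=False)
    outputs.append(p)

    edges = state.get("edges")
    if edges is None and "ppi_edges" in config.inputs:
        edges = annotation.read_edge_list(config.inputs["ppi_edges"])
    if edges is not None:
        rank = annotation.ppi_degree_rank(edges)
        p = out / "ppi_degree_rank.tsv"
        rank.to_csv(p, sep="\t", index=False)
        outputs.append(p)
    return ({}, outputs)


def _stage_profile(config: PipelineConfig, out: Path, state: dict):
    track_df = state.get("track_df")
    if track_df is not None:
        track = signal_profile.CoverageTrack.from_dataframe(track_df)
    else:
        track = signal_profile.load_track(config.inputs["coverage"])
    genes = _require(state, "genes", config,
                     lambda c: annotation.read_gene_table(c.inputs["genes"]))
    chrom_sizes = _require(state, "chrom_sizes", config,
                           lambda c: read_chrom_sizes(c.inputs["chrom_sizes"]))
    params = {"flank": 2000, "n_bins": 40, **config.profile}
    truth = state.get("truth")
    groups: dict[str, pd.DataFrame] = {}
    if truth is not None:
        groups["up"] = genes[genes["gene"].isin(truth.true_up)]
        groups["down"] = genes[genes["gene"].isin(truth.true_down)]
    else:
        groups["all"] = genes
    outputs = []
    profiles = {}
    for label, sub in groups.items():
        anchors = sub.rename(columns={"tss": "pos"})[["chrom", "pos", "strand"]]
        _, profile = signal_profile.anchor_matrix(
            track, anchors, chrom_sizes=chrom_sizes, **params
        )
        profiles[label] = profile
        p = out / f"profile_{label}.tsv"
        pd.DataFrame({"bin": np.arange(len(profile)), "mean_signal": profile}).to_csv(
            p, sep="\t", index=False
        )
        outputs.append(p)
    state["profiles"] = profiles
    return (params, outputs)


def _demo_pwm_counts() -> np.ndarray:
    """A sharp 10-bp demonstration motif (consensus ACGTACGTAC)."""
    consensus = "ACGTACGTAC"
    counts = np.full((4, len(consensus)), 1.0)
    for j, b in enumerate(consensus):
        counts["ACGT".index(b), j] = 20.0
    return counts


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "de": _stage_de,
    "rra": _stage_rra,
    "validate": _stage_validate,
    "cobind": _stage_cobind,
    "enrich": _stage_enrich,
    "annotate": _stage_annotate,
    "profile": _stage_profile,
}
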