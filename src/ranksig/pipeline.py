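"""Umbrella pipeline: simulate → GRP → panel → DE → compare → combine →
enrich → connect → TFCEP, with a manifest of every artifact written.

Each stage reads the in-memory products of its upstream stages, writes its
outputs as TSV/JSON with provenance headers into the output directory, and
records their SHA-256 digests in the manifest.  Disabling a stage makes any
downstream stage that needs it fail fast with an error naming the missing
stage.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import io as rio
from .coexpression import build_tfcep_bank, call_deviations, query_tfcep
from .differential import (
    collapse_probes,
    differential_profile,
    fold_change_counts,
    overlap_fisher,
    stouffer_combine,
    threshold_signature,
    DifferentialProfile,
)
from .enrichment import KSNullModel, enrich_collection
from .errors import PipelineError
from .connectivity import query_signature_bank
from .ranks import (
    build_grp,
    compendium_background_ranks,
    compute_scaled_ranks,
    rank_panel,
)
from .synth import (
    CELL_LINES,
    SimConfig,
    build_gene_set_collection,
    check_truth,
    default_config,
    generate_background_compendium,
    generate_coexpression_compendium,
    generate_experiment,
    generate_panel,
    generate_signature_bank,
)

__all__ = ["PipelineConfig", "run_pipeline", "STAGES"]

STAGES = (
    "simulate",
    "grp",
    "panel",
    "de",
    "compare",
    "combine",
    "enrich",
    "connect",
    "tfcep",
)

_NEEDS = {
    "grp": ("simulate",),
    "panel": ("grp",),
    "de": ("simulate",),
    "compare": ("de",),
    "combine": ("de",),
    "enrich": ("de", "simulate"),
    "connect": ("de",),
    "tfcep": ("de", "simulate"),
}


@dataclass
class PipelineConfig:
    """Stage toggles and every stage parameter of the end-to-end run."""

    outdir: str = "ranksig_out"
    seed: int = 0
    stages: dict[str, bool] = field(default_factory=lambda: {s: True for s in STAGES})
    z_cut_compare: float = 3.0  # "three standard deviations" overlap threshold
    z_cut_signature: float = 5.0  # "five standard deviations" signature threshold
    fold: float = 2.0
    ks_alpha: float = 0.3274679
    ks_beta: float = 0.3327016
    ks_gamma: float = 0.491337
    n_min: int = 5
    z_dev: float = 2.0
    k_partners: int = 500
    sim_overrides: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.stages = {**{s: True for s in STAGES}, **cfg.stages}
        return cfg

    def sim_config(self) -> SimConfig:
        cfg = default_config(self.seed)
        if self.sim_overrides:
            cfg = dataclasses.replace(cfg, **self.sim_overrides)
        return cfg


def _require(state: dict, stage: str, needed_key: str, needed_stage: str):
    if needed_key not in state:
        raise PipelineError(
            f"stage {stage!r} requires output of disabled/failed stage {needed_stage!r}"
        )
    return state[needed_key]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all enabled stages in dependency order; return the manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = {s for s in STAGES if config.stages.get(s, True)}
    for stage in enabled:
        for dep in _NEEDS.get(stage, ()):
            if dep not in enabled:
                raise PipelineError(
                    f"stage {stage!r} requires disabled stage {dep!r}"
                )

    state: dict = {}
    manifest: dict = {"seed": config.seed, "stages": {}}
    model = KSNullModel(config.ks_alpha, config.ks_beta, config.ks_gamma)

    def emit(stage: str, name: str, writer) -> Path:
        path = outdir / name
        writer(path)
        manifest["stages"].setdefault(stage, []).append(
            {"path": name, "sha256": rio.file_digest(path)}
        )
        return path

    sim = config.sim_config()
    prov = {"seed": config.seed}

    if "simulate" in enabled:
        experiment, pmap, truth = generate_experiment(sim)
        background = generate_background_compendium(sim)
        collection = build_gene_set_collection(sim)
        check_truth(truth, sim)
        state.update(
            experiment=experiment, pmap=pmap, truth=truth,
            background=background, collection=collection,
        )
        emit("simulate", "experiment.tsv",
             lambda p: rio.write_matrix(experiment, p, {**prov, "stage": "simulate"}))
        emit("simulate", "probe_map.tsv",
             lambda p: rio.write_probe_map(pmap, p, {**prov, "stage": "simulate"}))
        emit("simulate", "gene_sets.gmt",
             lambda p: rio.write_gmt(collection, p, {**prov, "stage": "simulate"}))
        for i, series in enumerate(background, start=1):
            emit("simulate", f"background_{i}.tsv",
                 lambda p, s=series: rio.write_matrix(s, p, {**prov, "stage": "simulate"}))

    if "grp" in enabled:
        experiment = _require(state, "grp", "experiment", "simulate")
        background = _require(state, "grp", "background", "simulate")
        pmap = state["pmap"]
        r0 = compendium_background_ranks(background)
        grps = {}
        for line in CELL_LINES:
            samples = experiment.samples_in_group(f"{line}:vehicle")
            r = compute_scaled_ranks(experiment, samples)
            grps[line] = build_grp(r, r0, pmap, name=line)
            emit("grp", f"grp_{line}.tsv",
                 lambda p, g=grps[line]: rio.write_rank_profile(g, p, {**prov, "stage": "grp"}))
        state["grps"] = grps

    if "panel" in enabled:
        grps = _require(state, "panel", "grps", "grp")
        panel = generate_panel(sim, grps["core"], grps["margin"], state.get("truth"))
        rows = {line: rank_panel(grps[line], panel) for line in CELL_LINES}
        state["panel"] = panel
        state["panel_ranking"] = rows

        def write_panel(path: Path) -> None:
            lines = [f"# stage: panel", f"# seed: {config.seed}", "line\tentity\trho\tz\tn"]
            for line_name, ranking in rows.items():
                for name, res in ranking:
                    lines.append(f"{line_name}\t{name}\t{res.rho:.6g}\t{res.z:.6g}\t{res.n}")
            path.write_text("\n".join(lines) + "\n")

        emit("panel", "panel_ranking.tsv", write_panel)

    if "de" in enabled:
        experiment = _require(state, "de", "experiment", "simulate")
        pmap = state["pmap"]
        profiles: dict[str, DifferentialProfile] = {}
        gene_profiles: dict[str, DifferentialProfile] = {}
        counts = {}
        for line in CELL_LINES:
            control = experiment.samples_in_group(f"{line}:vehicle")
            treated = experiment.samples_in_group(f"{line}:treated")
            probe_prof = differential_profile(experiment, control, treated)
            gene_prof = collapse_probes(probe_prof, pmap)
            profiles[line] = probe_prof
            gene_profiles[line] = gene_prof
            counts[line] = fold_change_counts(gene_prof, config.fold)
            emit("de", f"de_{line}_gene.tsv",
                 lambda p, g=gene_prof: rio.write_differential(g, p, {**prov, "stage": "de"}))
            sig = threshold_signature(gene_prof, config.z_cut_signature)
            state[f"signature_{line}"] = sig
            emit("de", f"signature_{line}.sig",
                 lambda p, s=sig: rio.write_signature(s, p, {**prov, "stage": "de"}))
        state["de_probe"] = profiles
        state["de_gene"] = gene_profiles
        emit("de", "fold_counts.json",
             lambda p: p.write_text(json.dumps(
                 {line: {"n_up": c[0], "n_down": c[1], "fold": config.fold}
                  for line, c in counts.items()}, indent=2) + "\n"))

    if "compare" in enabled:
        profiles = _require(state, "compare", "de_probe", "de")
        table = overlap_fisher(
            profiles["core"], profiles["margin"], config.z_cut_compare
        )
        emit("compare", "overlap.json",
             lambda p: p.write_text(json.dumps({
                 "uu": table.uu, "ud": table.ud, "du": table.du, "dd": table.dd,
                 "p": table.p, "direction": table.direction,
                 "z_cut": config.z_cut_compare}, indent=2) + "\n"))
        state["overlap"] = table

    if "combine" in enabled:
        gene_profiles = _require(state, "combine", "de_gene", "de")
        combined = stouffer_combine(gene_profiles["core"], gene_profiles["margin"])
        state["combined"] = combined
        table = combined.z.to_frame("z")
        table["log2fc"] = 0.0  # fold change is not defined for a combined profile
        combined_profile = DifferentialProfile(table, level="gene")
        state["combined_profile"] = combined_profile
        sig = threshold_signature(combined_profile, config.z_cut_signature)
        state["signature_combined"] = sig
        emit("combine", "combined_gene.tsv",
             lambda p: rio.write_differential(combined_profile, p, {**prov, "stage": "combine"}))
        emit("combine", "signature_combined.sig",
             lambda p: rio.write_signature(sig, p, {**prov, "stage": "combine"}))

    if "enrich" in enabled:
        gene_profiles = _require(state, "enrich", "de_gene", "de")
        collection = _require(state, "enrich", "collection", "simulate")
        for line in CELL_LINES:
            results = enrich_collection(gene_profiles[line], collection, model, config.n_min)

            def write_enrich(path: Path, res=results) -> None:
                lines = ["# stage: enrich", f"# seed: {config.seed}",
                         "set\tN\tM\td_max\td_min\tsigma\tz"]
                for r in res:
                    lines.append(
                        f"{r.name}\t{r.n}\t{r.m}\t{r.d_max:.6g}\t{r.d_min:.6g}"
                        f"\t{r.sigma:.6g}\t{r.z:.6g}"
                    )
                path.write_text("\n".join(lines) + "\n")

            emit("enrich", f"enrichment_{line}.tsv", write_enrich)

    if "connect" in enabled:
        query = _require(state, "connect", "signature_core", "de")
        bank = generate_signature_bank(sim, query)
        state["drug_bank"] = bank
        result = query_signature_bank(query, bank)
        state["connectivity"] = result
        emit("connect", "connectivity.tsv",
             lambda p: p.write_text(
                 "# stage: connect\n"
                 + result.to_frame().to_csv(sep="\t", index=False, float_format="%.6g")))

    if "tfcep" in enabled:
        query = _require(state, "tfcep", "signature_core", "de")
        compendium = generate_coexpression_compendium(sim)
        calls = call_deviations(compendium, config.z_dev)
        tf_list = [entry[0] for entry in sim.planted_tf_modules]
        bank = build_tfcep_bank(calls, tf_list, k=config.k_partners)
        result = query_tfcep(query, bank)
        state["tfcep"] = result
        emit("tfcep", "tfcep_ranking.tsv",
             lambda p: p.write_text(
                 "# stage: tfcep\n"
                 + result.to_frame().to_csv(sep="\t", index=False, float_format="%.6g")))

    if "truth" in state:
        # written last: the panel stage may add the twin identity
        emit("simulate", "truth.json", lambda p: rio.write_truth(state["truth"], p))

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
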