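"""End-to-end pipeline: ingest/simulate -> aggregate -> [rarefy] -> dedupe ->
diversity -> ordination + trait fitting + Procrustes -> phylogenetic signal
-> host-filter null model.

A single YAML (or dict) configuration drives all stages; one master seed is
split into independent per-stage streams, and rerunning with an identical
config and seed reproduces every artifact bit-identically.  The run report
records stage timings, seeds, and SHA-256 checksums of all artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diversity as dv
from . import hostfilter as hf
from . import ordination as ord_
from . import phylosignal as ps
from . import synthdata as sd
from .tables import (
    FunctionTable,
    dedupe_correlated,
    read_function_table,
    read_hierarchy,
    read_phylogeny,
    read_trait_table,
    relative_abundance,
    rarefy,
)

logger = logging.getLogger(__name__)

STAGES = ("diversity", "ordination", "signal", "filter")


@dataclass
class PipelineConfig:
    """Validated pipeline configuration with study-default parameters."""

    out_dir: str = "phyllomatch_out"
    seed: int = 0
    # inputs: either file paths ...
    counts: str | None = None
    sample_map: str | None = None
    hierarchy: str | None = None
    traits: str | None = None
    tree: str | None = None
    # ... or a simulate block (dict of SimulationParams overrides)
    simulate: dict | None = None
    # stage toggles
    stages: list[str] = field(default_factory=lambda: list(STAGES))
    # stage parameters
    rarefy_depth: int = 20100
    rarefy_enabled: bool = False  # off by default for functional tables
    analysis_level: str = "tier3"
    diversity_levels: list[str] = field(default_factory=lambda: ["tier1", "tier2", "tier3", "gene"])
    weighting: str = "size_proportional"
    n_perm: int = 999  # trait-fit permutations
    n_rand: int = 9999  # signal + null-model randomizations
    alpha: float = 0.05
    upper_quantile: float = 0.95
    lower_quantile: float = 0.05
    null_algorithm: str = "patefield"
    signal_transform: str = "none"  # or "log1p"
    top_k: int = 20
    n_axes: int = 2


#: profile presets; "paper" keeps the full 9999 randomizations
PROFILES = {
    "paper": {"n_rand": 9999, "n_perm": 999},
    "test": {"n_rand": 999, "n_perm": 199},
}


def validate_config(raw: dict | str | Path, profile: str | None = None) -> PipelineConfig:
    """Normalize and validate a raw config (dict or YAML path).

    All problems are reported at once.  Unknown keys are errors.
    """
    if isinstance(raw, (str, Path)):
        with open(raw) as fh:
            raw = yaml.safe_load(fh) or {}
    raw = dict(raw)
    if profile:
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; choose from {sorted(PROFILES)}")
        for k, v in PROFILES[profile].items():
            raw.setdefault(k, v)
    known = {f.name for f in fields(PipelineConfig)}
    errors = [f"unknown config key: {k!r}" for k in raw if k not in known]
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    if not 0 < cfg.alpha <= 1:
        errors.append(f"alpha must be in (0, 1], got {cfg.alpha}")
    if not (0 < cfg.lower_quantile < cfg.upper_quantile < 1):
        errors.append("need 0 < lower_quantile < upper_quantile < 1")
    if cfg.n_perm < 1 or cfg.n_rand < 1:
        errors.append("n_perm and n_rand must be >= 1")
    if cfg.rarefy_depth < 1:
        errors.append("rarefy_depth must be >= 1")
    if cfg.top_k < 1:
        errors.append("top_k must be >= 1")
    if cfg.n_axes < 1:
        errors.append("n_axes must be >= 1")
    if cfg.signal_transform not in ("none", "log1p"):
        errors.append(f"signal_transform must be 'none' or 'log1p', got {cfg.signal_transform!r}")
    unknown_stages = [s for s in cfg.stages if s not in STAGES]
    if unknown_stages:
        errors.append(f"unknown stage(s): {unknown_stages}")
    if cfg.simulate is None:
        for key in ("counts", "hierarchy", "traits", "tree"):
            if getattr(cfg, key) is None:
                errors.append(f"missing input path {key!r} (and no simulate block)")
            elif not Path(getattr(cfg, key)).exists():
                errors.append(f"input file not found: {getattr(cfg, key)}")
    else:
        sim_known = {f.name for f in fields(sd.SimulationParams)}
        errors += [f"unknown simulate key: {k!r}" for k in cfg.simulate if k not in sim_known]
    if errors:
        raise ValueError("invalid configuration:\n  " + "\n  ".join(errors))
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _stage_seed(master: int, label: str) -> int:
    digest = hashlib.blake2b(f"{label}|{master}".encode(), digest_size=4).digest()
    return int.from_bytes(digest, "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order and write all artifacts.

    Returns the run report (also written to ``report.json``).  A stage
    failure aborts the run; artifacts written so far are retained and listed
    in a MANIFEST file marked incomplete.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "config_echo.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)
    report: dict = {"seed": config.seed, "stages": {}, "artifacts": {}}
    artifacts: list[Path] = [out / "config_echo.yaml"]
    current_stage = "ingest"

    def finish_stage(name: str, t0: float, new_paths: list[Path]) -> None:
        report["stages"][name] = {"seconds": round(time.perf_counter() - t0, 3)}
        artifacts.extend(new_paths)
        logger.info("stage %s done (%.2fs)", name, report["stages"][name]["seconds"])

    try:
        # ---- ingest / simulate -------------------------------------------
        t0 = time.perf_counter()
        if config.simulate is not None:
            params = sd.SimulationParams(**config.simulate)
            if "seed" not in config.simulate:
                params.seed = _stage_seed(config.seed, "simulate")
            dataset = sd.simulate_dataset(params)
            paths = dataset.write(out / "inputs")
            gene_table, hierarchy, traits, tree = (
                dataset.table, dataset.hierarchy, dataset.traits, dataset.tree,
            )
            truth = dataset.truth
            finish_stage("simulate", t0, list(paths.values()))
        else:
            gene_table = read_function_table(config.counts, mapping_path=config.sample_map)
            hierarchy = read_hierarchy(config.hierarchy)
            traits = read_trait_table(config.traits)
            tree = read_phylogeny(config.tree)
            truth = None
            finish_stage("ingest", t0, [])

        # ---- rarefy (optional) -------------------------------------------
        if config.rarefy_enabled:
            current_stage = "rarefy"
            t0 = time.perf_counter()
            gene_table = rarefy(gene_table, config.rarefy_depth, _stage_seed(config.seed, "rarefy"))
            finish_stage("rarefy", t0, [])

        # ---- aggregate + dedupe ------------------------------------------
        current_stage = "aggregate"
        t0 = time.perf_counter()
        from .tables import aggregate_to_tier

        analysis_table = aggregate_to_tier(gene_table, hierarchy, config.analysis_level)
        rel = relative_abundance(analysis_table)
        dedupe = dedupe_correlated(rel)
        with open(out / "dedupe.json", "w") as fh:
            json.dump({"mapping": dedupe.mapping, "constant": dedupe.constant}, fh, indent=2, sort_keys=True)
        finish_stage("aggregate", t0, [out / "dedupe.json"])

        # ---- diversity ----------------------------------------------------
        if "diversity" in config.stages:
            current_stage = "diversity"
            t0 = time.perf_counter()
            partitions = dv.partition_by_level(
                gene_table, hierarchy, config.diversity_levels, weighting=config.weighting
            )
            dv.write_diversity_report(partitions, out / "diversity.tsv", out / "diversity.json")
            report["diversity"] = {p.level: p.beta_pct for p in partitions}
            finish_stage("diversity", t0, [out / "diversity.tsv", out / "diversity.json"])

        # ---- ordination + traits + Procrustes ----------------------------
        if "ordination" in config.stages:
            current_stage = "ordination"
            t0 = time.perf_counter()
            ordn = ord_.pca(dedupe.matrix)
            ordn.scores.round(10).to_csv(out / "ordination_scores.tsv", sep="\t", lineterminator="\n")
            ordn.loadings.round(10).to_csv(out / "ordination_loadings.tsv", sep="\t", lineterminator="\n")
            ordn.contributions.round(10).to_csv(out / "ordination_contributions.tsv", sep="\t", lineterminator="\n")
            axes = tuple(range(1, min(config.n_axes, len(ordn.axes)) + 1))
            top = ord_.top_contributors(ordn, k=config.top_k, axes=axes)
            top.round(10).to_csv(out / "top_contributors.tsv", sep="\t", lineterminator="\n")
            fits = ord_.fit_traits(
                ordn, traits, gene_table.sample_to_host, axes=axes,
                n_perm=config.n_perm, seed=_stage_seed(config.seed, "envfit"),
            )
            ord_.trait_fit_table(fits).round(10).to_csv(out / "trait_fits.tsv", sep="\t", lineterminator="\n")
            tv = ord_.variance_explained_by_traits(dedupe.matrix, traits, gene_table.sample_to_host)
            with open(out / "trait_variance.json", "w") as fh:
                json.dump(
                    {"raw": tv.raw, "adjusted": tv.adjusted, "n_samples": tv.n_samples,
                     "traits_used": tv.traits_used, "traits_dropped": tv.traits_dropped},
                    fh, indent=2, sort_keys=True,
                )
            new = [out / p for p in (
                "ordination_scores.tsv", "ordination_loadings.tsv", "ordination_contributions.tsv",
                "top_contributors.tsv", "trait_fits.tsv", "trait_variance.json",
            )]
            # Procrustes over hosts with exactly two samples, pairing the two
            # replicates' coordinates in the ordination plane
            pairs = {h: s for h, s in gene_table.host_samples().items() if len(s) == 2}
            if len(pairs) >= 2:
                cols = [f"PC{a}" for a in axes]
                A = ordn.scores.loc[[s[0] for s in pairs.values()], cols].to_numpy()
                B = ordn.scores.loc[[s[1] for s in pairs.values()], cols].to_numpy()
                pr = ord_.procrustes(A, B)
                ord_.write_procrustes(pr, out / "procrustes.json")
                report["procrustes_correlation"] = pr.correlation
                new.append(out / "procrustes.json")
            report["trait_variance"] = {"raw": tv.raw, "adjusted": tv.adjusted}
            finish_stage("ordination", t0, new)

        # ---- phylogenetic signal -----------------------------------------
        if "signal" in config.stages:
            current_stage = "signal"
            t0 = time.perf_counter()
            per_host = ps.one_sample_per_species(analysis_table, _stage_seed(config.seed, "subsample"))
            host_rel = relative_abundance(per_host)
            results = ps.signal_all(
                tree, host_rel, n_rand=config.n_rand,
                seed=_stage_seed(config.seed, "signal"), transform=config.signal_transform,
            )
            ps.signal_table(results).round(10).to_csv(out / "signal.tsv", sep="\t", lineterminator="\n")
            selected, matrix = ps.select_signal_functions(results, alpha=config.alpha, abundance=host_rel)
            with open(out / "signal_selected.json", "w") as fh:
                json.dump([r.function_id for r in selected], fh, indent=2)
            new = [out / "signal.tsv", out / "signal_selected.json"]
            if matrix is not None and matrix.shape[1]:
                matrix.round(10).to_csv(out / "signal_matrix.tsv", sep="\t", lineterminator="\n")
                new.append(out / "signal_matrix.tsv")
            report["signal"] = {
                "n_tested": len(results),
                "n_selected": len(selected),
                "selected": [r.function_id for r in selected],
            }
            finish_stage("signal", t0, new)

        # ---- host-filter null model --------------------------------------
        if "filter" in config.stages:
            current_stage = "filter"
            t0 = time.perf_counter()
            nm = hf.NullModelConfig(
                n_randomizations=config.n_rand,
                upper_quantile=config.upper_quantile,
                lower_quantile=config.lower_quantile,
                algorithm=config.null_algorithm,
                seed=_stage_seed(config.seed, "filter"),
            )
            fm = hf.null_flags(analysis_table, nm)
            summary = hf.tally_flags(fm, level=config.analysis_level)
            hf.write_filter_outputs(
                [(fm, summary)], out / "filter_flags.tsv", out / "filter_summary.tsv", out / "filter_summary.json",
            )
            report["filter"] = summary.to_dict()
            finish_stage("filter", t0, [out / p for p in ("filter_flags.tsv", "filter_summary.tsv", "filter_summary.json")])

        # ---- recovery diagnostics when ground truth is known -------------
        if truth is not None and "signal" in config.stages and "ordination" in config.stages:
            planted = set(truth.selected_function_ids)
            sel = set(report.get("signal", {}).get("selected", []))
            topset = set(top.index)
            report["recovery"] = {
                "n_planted": len(planted),
                "signal_recall": len(planted & sel) / len(planted) if planted else None,
                "top_contributor_recall": len(planted & topset) / len(planted) if planted else None,
            }

    except Exception as exc:
        manifest = {"complete": False, "failed_stage": current_stage, "error": str(exc),
                    "artifacts": [str(p) for p in artifacts]}
        with open(out / "MANIFEST.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        raise RuntimeError(f"pipeline stage {current_stage!r} failed: {exc}") from exc

    report["artifacts"] = {str(p.relative_to(out)): _sha256(p) for p in artifacts if p.exists()}
    with open(out / "MANIFEST.json", "w") as fh:
        json.dump({"complete": True, "artifacts": sorted(report["artifacts"])}, fh, indent=2)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report
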