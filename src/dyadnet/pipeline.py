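"""End-to-end orchestration: ingest -> SRI matrices -> hurdle GLMMs ->
permutation tests -> contrasts -> sociograms, with a reproducible manifest.

The default model ladder mirrors the analysis structure: one beta model for
the 10 m party-co-residence index, and binomial occurrence plus beta
magnitude models (a hurdle pair) for the 1 m direct-proximity and grooming
indices. Every model is compared full (with the group x dyad-sex
interaction) versus reduced (mains retained) by analytic LRT and, when
``n_perm > 0``, by datastream permutation.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from datetime import date as Date
from pathlib import Path
from typing import Dict, List, Optional, Tuple

import numpy as np
import yaml

from . import __version__
from .association import MEASURES, build_daily_stream, matrix_from_stream, table_from_stream, write_matrix
from .data_model import (
    Individual,
    enumerate_dyads_by_group,
    load_focal_records,
    load_roster,
    write_focal_records,
    write_roster,
)
from .inference import (
    FULL_TERMS,
    REDUCED_TERMS,
    FitOptions,
    GLMMFit,
    ModelSpec,
    RESPONSES,
    fit_full_reduced,
    group_contrasts,
    likelihood_ratio,
)
from .permutation import format_p_rand, run_permutation_test
from .sociogram import build_graph, draw_sociogram, export_edgelist, export_graphml, layout_fr, spinglass_communities
from .synthetic import GeneratorConfig, GroupSpec, generate_focal_stream, generate_roster

logger = logging.getLogger("dyadnet")

__all__ = ["RunConfig", "run_pipeline", "summarize_results", "DEFAULT_LADDER"]

#: (name, response) pairs of the default model ladder
DEFAULT_LADDER = (
    ("party", "party_sri"),
    ("direct_occurrence", "occurrence"),
    ("direct_magnitude", "magnitude_sri"),
    ("grooming_occurrence", "grooming_occurrence"),
    ("grooming_magnitude", "grooming_magnitude"),
)


@dataclass
class RunConfig:
    output_dir: str = "dyadnet_run"
    roster_path: Optional[str] = None
    focal_path: Optional[str] = None
    generator: Optional[GeneratorConfig] = None
    measures: Tuple[str, ...] = MEASURES
    ladder: Tuple[Tuple[str, str], ...] = DEFAULT_LADDER
    n_perm: int = 1000
    seed: int = 0
    min_age: float = 4.0
    permutation_scheme: str = "uniform-day"
    re_structure: str = "crossed"
    polish: bool = True

    def __post_init__(self) -> None:
        has_paths = self.roster_path is not None and self.focal_path is not None
        has_gen = self.generator is not None
        if has_paths == has_gen:
            raise ValueError("exactly one of (roster_path + focal_path) or generator settings must be given")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        gen = raw.pop("generator", None)
        if gen is not None:
            groups = tuple(GroupSpec(**g) for g in gen.pop("groups", []))
            effects = {}
            for key, val in (gen.pop("beta_sextype_by_group", None) or {}).items():
                gid, st = key.split(":")
                effects[(gid, st)] = float(val)
            start = gen.pop("start_date", None)
            kwargs = dict(gen)
            if groups:
                kwargs["groups"] = groups
            if effects:
                kwargs["beta_sextype_by_group"] = effects
            if start:
                kwargs["start_date"] = Date.fromisoformat(str(start))
            raw["generator"] = GeneratorConfig(**kwargs)
        if "ladder" in raw:
            raw["ladder"] = tuple((str(a), str(b)) for a, b in raw["ladder"])
        if "measures" in raw:
            raw["measures"] = tuple(raw["measures"])
        return cls(**raw)

    def to_jsonable(self) -> Dict:
        d = asdict(self)
        if self.generator is not None:
            g = asdict(self.generator)
            g["groups"] = [asdict(gr) for gr in self.generator.groups]
            g["beta_sextype_by_group"] = {f"{k[0]}:{k[1]}": v for k, v in self.generator.beta_sextype_by_group.items()}
            g["start_date"] = self.generator.start_date.isoformat()
            d["generator"] = g
        return d


def _fit_to_dict(fit: GLMMFit) -> Dict:
    return {
        "response": fit.spec.response,
        "family": fit.spec.family,
        "terms": fit.terms,
        "estimates": [float(v) for v in fit.beta_hat],
        "se": [float(v) for v in fit.se],
        "phi": fit.phi_hat,
        "sigma2_a": fit.sigma2_a,
        "sigma2_b": fit.sigma2_b,
        "loglik": fit.loglik,
        "deviance": fit.deviance,
        "n_obs": fit.n_obs,
        "converged": fit.converged,
        "n_squeezed": fit.n_squeezed,
    }


def run_pipeline(config: RunConfig) -> Dict:
    """Run every stage and write all artifacts; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s %(message)s"))
    logger.addHandler(handler)
    manifest: Dict = {
        "version": __version__,
        "config": config.to_jsonable(),
        "seeds": {"master": config.seed},
        "warnings": [],
        "artifacts": [],
        "models": {},
        "skipped": [],
    }

    def artifact(name: str) -> Path:
        manifest["artifacts"].append(name)
        return out / name

    try:
        if config.generator is not None:
            roster = generate_roster(config.generator)
            records = generate_focal_stream(roster, config.generator)
            write_roster(roster, artifact("roster.csv"))
            write_focal_records(records, artifact("focal_records.csv"))
            manifest["seeds"]["generator"] = config.generator.seed
        else:
            roster = load_roster(config.roster_path, min_age=config.min_age)
            records = load_focal_records(config.focal_path, roster)

        stream = build_daily_stream(records, roster)
        table = table_from_stream(stream)
        table.to_csv(artifact("dyad_table.csv"), index=False)
        matrices = {}
        for measure in config.measures:
            matrices[measure] = matrix_from_stream(stream, measure)
            write_matrix(matrices[measure], artifact(f"sri_matrix_{measure}.csv"))

        options = FitOptions(polish=config.polish, seed=config.seed)
        perm_index = 0
        for name, response in config.ladder:
            measure_col = RESPONSES[response][0]
            part = RESPONSES[response][2]
            family = RESPONSES[response][1]
            values = table[measure_col].to_numpy()
            if part == "magnitude" and int((values > 0).sum()) < len(FULL_TERMS) + 3:
                manifest["skipped"].append({"model": name, "reason": "too few nonzero dyads"})
                continue
            if part != "magnitude" and np.all(values == 0):
                manifest["skipped"].append({"model": name, "reason": "all-zero stream"})
                continue
            spec_full = ModelSpec(response=response, fixed_terms=FULL_TERMS, family=family,
                                  re_structure=config.re_structure)
            spec_reduced = ModelSpec(response=response, fixed_terms=REDUCED_TERMS, family=family,
                                     re_structure=config.re_structure)
            full, reduced = fit_full_reduced(table, spec_full, spec_reduced, options)
            lrt = likelihood_ratio(full, reduced)
            entry = {
                "full": _fit_to_dict(full),
                "reduced": _fit_to_dict(reduced),
                "lrt": {"chi2": lrt.chi2, "df": lrt.df, "p_analytic": lrt.p_analytic},
            }
            try:
                contrasts = group_contrasts(full)
                entry["contrasts"] = [
                    {"level": c.level, "estimate": c.estimate, "se": c.se, "statistic": c.statistic, "p": c.p}
                    for c in contrasts
                ]
            except ValueError as exc:
                entry["contrasts"] = None
                manifest["warnings"].append(f"contrasts for {name}: {exc}")
            if config.n_perm > 0:
                perm_seed = (config.seed * 1000 + 7919 * perm_index) % (2**31 - 1)
                perm_index += 1
                result = run_permutation_test(
                    records, roster, response=response, n_perm=config.n_perm,
                    seed=perm_seed, scheme=config.permutation_scheme,
                    options=options, stream=stream,
                )
                manifest["seeds"][f"permutation_{name}"] = perm_seed
                entry["permutation"] = {
                    "n_perm": result.n_perm,
                    "observed_delta": result.observed_delta,
                    "p_rand": result.p_rand,
                    "p_rand_display": format_p_rand(result),
                    "n_failed": result.n_failed,
                    "warning": result.warning,
                }
                np.savetxt(artifact(f"null_deltas_{name}.txt"), result.null_deltas, fmt="%.8g")
            manifest["models"][name] = entry
            with open(artifact(f"model_{name}.json"), "w") as fh:
                json.dump(entry, fh, indent=1, sort_keys=True)

        for measure in config.measures:
            sg = build_graph(matrices[measure], roster)
            layout_fr(sg, seed=config.seed)
            if sg.graph.number_of_edges() > 0:
                spinglass_communities(sg, seed=config.seed)
            else:
                sg.communities = {v: i for i, v in enumerate(sorted(sg.graph.nodes))}
                sg.hamiltonian = 0.0
            export_graphml(sg, artifact(f"sociogram_{measure}.graphml"))
            export_edgelist(sg, artifact(f"sociogram_{measure}_edges.csv"))
            draw_sociogram(sg, artifact(f"sociogram_{measure}.svg"))
            manifest.setdefault("sociograms", {})[measure] = {
                "n_edges": sg.graph.number_of_edges(),
                "n_communities": len(set(sg.communities.values())),
                "hamiltonian": sg.hamiltonian,
            }
    except Exception as exc:
        logger.removeHandler(handler)
        handler.close()
        raise RuntimeError(f"pipeline stage failed: {exc}") from exc

    cfg_text = json.dumps(manifest["config"], sort_keys=True)
    manifest["config_hash"] = hashlib.sha256(cfg_text.encode()).hexdigest()[:16]
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    logger.removeHandler(handler)
    handler.close()
    return manifest


def summarize_results(run_dir) -> str:
    """Human-readable report mirroring the reporting shape of the analysis."""
    run_dir = Path(run_dir)
    manifest_path = run_dir / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {run_dir}")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    lines: List[str] = []
    lines.append(f"dyadnet run (version {manifest['version']}, config {manifest.get('config_hash', '?')})")
    lines.append("")
    for name, entry in manifest.get("models", {}).items():
        lrt = entry["lrt"]
        lines.append(f"== {name} ({entry['full']['family']}, n = {entry['full']['n_obs']}) ==")
        lines.append(
            f"  group x dyad-sex interaction: chi2 = {lrt['chi2']:.2f}, df = {lrt['df']}, "
            f"analytic p = {lrt['p_analytic']:.4g}"
        )
        perm = entry.get("permutation")
        if perm:
            lines.append(
                f"  P_rand = {perm['p_rand_display']} ({perm['n_perm']} permutations, "
                f"{perm['n_failed']} failed fits)"
            )
        full = entry["full"]
        for term, est, se in zip(full["terms"], full["estimates"], full["se"]):
            lines.append(f"    {term:<28s} {est:+8.3f} +/- {se:.3f}")
        if entry.get("contrasts"):
            for c in entry["contrasts"]:
                lines.append(
                    f"  contrast {c['level']}: group1 - group2 = {c['estimate']:+.3f} "
                    f"+/- {c['se']:.3f} (t = {c['statistic']:.2f}, p = {c['p']:.3g})"
                )
        if not full["converged"]:
            lines.append("  WARNING: full model flagged non-converged")
        lines.append("")
    for entry in manifest.get("skipped", []):
        lines.append(f"skipped {entry['model']}: {entry['reason']}")
    for measure, info in manifest.get("sociograms", {}).items():
        lines.append(
            f"sociogram {measure}: {info['n_edges']} edges, {info['n_communities']} communities "
            f"(H = {info['hamiltonian']:.4f})"
        )
    missing = [a for a in manifest.get("artifacts", []) if not (run_dir / a).exists()]
    if missing:
        lines.append("")
        lines.append(f"INCOMPLETE RUN — missing artifacts: {', '.join(missing)}")
    return "\n".join(lines)
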