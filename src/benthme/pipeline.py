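"""End-to-end orchestration: simulate (or load) -> ANCOVA + ME tests ->
community analysis -> descriptive summaries, with deterministic seeding
and a reproducibility manifest.

Stage seeds are derived as a stable hash of (master seed, stage name), so
adding a stage never shifts the random streams of existing ones.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .ancova import ancova_report, fit_mixed_ancova
from .community import (
    Npmanova,
    bray_curtis,
    build_community_matrix,
    centroids_ci,
    nmds,
    pairwise_permutation,
)
from .design import DesignSpec
from .effects import EffectSizeSpec, default_effect_sizes, me_test
from .simulate import SimParams, TAXA, default_params, simulate_biomass
from .summaries import (
    DEFAULT_THRESHOLDS,
    cutoff_percentages,
    group_summary_ci,
    rank_dominants,
)
from .validate import validate_survey_csv

__all__ = ["PipelineConfig", "stage_seed", "run_pipeline"]


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    digest = hashlib.blake2b(
        f"{master_seed}:{stage}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "big") % (2**31 - 1)


@dataclass
class PipelineConfig:
    """Everything needed to reproduce a full pipeline run."""

    input: str = "simulate"  # "simulate" or a survey CSV path
    design: DesignSpec = field(default_factory=DesignSpec)
    params: SimParams | None = None
    alpha: float = 0.05
    effect_sizes: tuple[EffectSizeSpec, ...] = field(
        default_factory=default_effect_sizes
    )
    min_prevalence: float = 0.05
    n_perm: int = 9999
    nmds_k: int = 2
    nmds_starts: int = 20
    nmds_max_iter: int = 500
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    seed: int = 0

    def validate(self) -> None:
        self.design.validate()
        if self.params is not None:
            self.params.validate()
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.n_perm < 99:
            raise ValueError("n_perm must be >= 99")

    def to_dict(self) -> dict:
        return {
            "input": self.input,
            "design": self.design.to_dict(),
            "params": None if self.params is None else self.params.to_dict(),
            "alpha": self.alpha,
            "effect_sizes": [[s.label, s.f] for s in self.effect_sizes],
            "min_prevalence": self.min_prevalence,
            "n_perm": self.n_perm,
            "nmds_k": self.nmds_k,
            "nmds_starts": self.nmds_starts,
            "nmds_max_iter": self.nmds_max_iter,
            "thresholds": list(self.thresholds),
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return cls(
            input=d.get("input", "simulate"),
            design=DesignSpec.from_dict(d["design"]) if "design" in d else DesignSpec(),
            params=SimParams.from_dict(d["params"]) if d.get("params") else None,
            alpha=d.get("alpha", 0.05),
            effect_sizes=tuple(
                EffectSizeSpec(label, f)
                for label, f in d.get(
                    "effect_sizes", [["small", 0.2], ["medium", 0.5], ["large", 0.8]]
                )
            ),
            min_prevalence=d.get("min_prevalence", 0.05),
            n_perm=d.get("n_perm", 9999),
            nmds_k=d.get("nmds_k", 2),
            nmds_starts=d.get("nmds_starts", 20),
            nmds_max_iter=d.get("nmds_max_iter", 500),
            thresholds=tuple(d.get("thresholds", DEFAULT_THRESHOLDS)),
            seed=d.get("seed", 0),
        )

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path) -> int:
    df.to_csv(path, index=False)
    return len(df)


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> dict:
    """Run all stages in order; returns (and writes) the run manifest.

    Outputs under ``out_dir``: survey.csv, ancova_report.csv, me_tests.csv,
    dissimilarity.csv, ordination.csv, centroids.csv, npmanova.csv,
    pairwise.csv, cutoffs.csv, rankings.csv, group_ci.csv, manifest.json.
    Identical configs yield byte-identical outputs.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts: dict[str, int] = {}
    seeds = {s: stage_seed(config.seed, s) for s in ("simulate", "community")}

    # --- stage: survey table -------------------------------------------
    try:
        if config.input == "simulate":
            params = config.params or default_params()
            table = simulate_biomass(config.design, params, seeds["simulate"])
        else:
            table = validate_survey_csv(config.input)
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"stage 'survey' failed: {exc}") from exc
    counts["survey"] = _write_csv(table, out / "survey.csv")

    # --- stage: ANCOVA + ME tests --------------------------------------
    try:
        responses = [t for t in TAXA if t != "other"] + ["total_prey"]
        fits = [fit_mixed_ancova(table, r) for r in responses]
        report = ancova_report(fits, config.effect_sizes, config.alpha)
        me_rows = []
        for fit in fits:
            for _, r in fit.effect_table.iterrows():
                for spec in config.effect_sizes:
                    res = me_test(r["F"], r["df1"], r["df2"], spec, config.alpha)
                    me_rows.append(
                        {
                            "response": fit.response,
                            "effect": r["effect"],
                            "effect_size": spec.label,
                            "f": spec.f,
                            "F_obs": res.F_obs,
                            "df1": res.df1,
                            "df2": res.df2,
                            "lambda": res.lam,
                            "F_crit": res.F_crit,
                            "p_me": res.p_me,
                            "rejected": res.rejected,
                        }
                    )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'ancova' failed: {exc}") from exc
    counts["ancova_report"] = _write_csv(report, out / "ancova_report.csv")
    counts["me_tests"] = _write_csv(pd.DataFrame(me_rows), out / "me_tests.csv")

    # --- stage: community ----------------------------------------------
    try:
        cm = build_community_matrix(table, config.min_prevalence)
        D = bray_curtis(cm)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ordination = nmds(
                D,
                k=config.nmds_k,
                n_starts=config.nmds_starts,
                max_iter=config.nmds_max_iter,
                seed=seeds["community"],
            )
        grouping = "P" + cm.meta["period"].astype(str) + "-" + cm.meta["zone"]
        cents = centroids_ci(ordination, grouping)
        npm = Npmanova(cm).fit(n_perm=config.n_perm, seed=seeds["community"])
        pairs = pairwise_permutation(
            cm, n_perm=min(config.n_perm, 999), seed=seeds["community"],
            alpha=config.alpha,
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'community' failed: {exc}") from exc
    D.values.to_csv(out / "dissimilarity.csv")
    counts["dissimilarity"] = len(D.values)
    coords = ordination.coords.copy()
    coords["stress"] = ordination.stress
    coords.to_csv(out / "ordination.csv")
    counts["ordination"] = len(coords)
    cents.to_csv(out / "centroids.csv")
    counts["centroids"] = len(cents)
    counts["npmanova"] = _write_csv(npm.table, out / "npmanova.csv")
    counts["pairwise"] = _write_csv(pairs, out / "pairwise.csv")

    # --- stage: summaries ----------------------------------------------
    try:
        cutoffs = cutoff_percentages(table, thresholds=config.thresholds)
        rankings = rank_dominants(table)
        cis = pd.concat(
            [
                group_summary_ci(table, g).assign(group=g)
                for g in list(TAXA) + ["total_prey"]
            ],
            ignore_index=True,
        )
    except Exception as exc:  # noqa: BLE001
        raise RuntimeError(f"stage 'summaries' failed: {exc}") from exc
    counts["cutoffs"] = _write_csv(cutoffs, out / "cutoffs.csv")
    counts["rankings"] = _write_csv(rankings, out / "rankings.csv")
    counts["group_ci"] = _write_csv(cis, out / "group_ci.csv")

    manifest = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "stage_seeds": seeds,
        "row_counts": counts,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=float))
    return manifest
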