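"""Baseline-characteristics table, two-group tests, and pipeline
orchestration.

Categorical characteristics are compared with Pearson's chi-square test
(no continuity correction); continuous ones with the unpaired pooled
Student's t-test (Welch's correction available behind a flag, and
recommended in practice when arm variances differ)."""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from . import arm_network, cohort_builder, psm, survival_stats
from .errors import ConfigurationError, DataError
from .synthetic_claims import (
    ClaimsBundle,
    GeneratorConfig,
    generate_bundle,
    read_bundle,
    write_bundle,
)

log = logging.getLogger(__name__)


def chi_square_test(table) -> tuple[float, int, float]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, degrees of freedom, p).  Zero expected cells raise
    a data error suggesting a category merge.
    """
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise DataError("chi-square needs an r x c table with r, c >= 2")
    row = obs.sum(axis=1, keepdims=True)
    col = obs.sum(axis=0, keepdims=True)
    n = obs.sum()
    if n <= 0:
        raise DataError("chi-square: empty table")
    expected = row @ col / n
    if (expected <= 0).any():
        raise DataError(
            "chi-square: zero expected count; merge sparse categories")
    statistic = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    return statistic, df, float(stats.chi2.sf(statistic, df))


def t_test_unpaired(x, y, equal_variance: bool = True) -> tuple[float, float, float]:
    """Unpaired two-sample t-test; pooled-variance Student's t by default,
    Welch's unequal-variance form when ``equal_variance`` is False.

    Returns (statistic, degrees of freedom, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 < 2 or n2 < 2:
        raise DataError("t-test needs at least two observations per arm")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if equal_variance:
        sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
        if sp2 <= 0:
            raise DataError("t-test: zero pooled variance")
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / n1 + 1 / n2))
        df = float(n1 + n2 - 2)
    else:
        se2 = v1 / n1 + v2 / n2
        if se2 <= 0:
            raise DataError("t-test: zero variance")
        t = (x.mean() - y.mean()) / np.sqrt(se2)
        df = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
    return float(t), float(df), float(2 * stats.t.sf(abs(t), df))


def format_p(p: float) -> str:
    """Three-decimal p-value rendering with the conventional floor."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


# ---------------------------------------------------------------------------
# Baseline table

_CATEGORICAL = [
    ("age_band", ("lt30", "30to40", "ge40")),
    ("sex", ("M", "F")),
    ("cci_group", ("0", "1-2", ">=3")),
]
_CONTINUOUS = [
    "index_duration_days", "ddd_total", "ddd_nrti", "ddd_pi", "ddd_nnrti",
    "ddd_insti", "ddd_combined_art", "cci_score",
]


def _arm_rows(users: pd.DataFrame, nonusers: pd.DataFrame, sample: str):
    rows = []
    for col, levels in _CATEGORICAL:
        table = [
            [int((users[col] == lv).sum()) for lv in levels],
            [int((nonusers[col] == lv).sum()) for lv in levels],
        ]
        try:
            statistic, _, p = chi_square_test(table)
        except DataError:
            statistic, p = np.nan, np.nan
        for i, lv in enumerate(levels):
            rows.append({
                "sample": sample, "characteristic": col, "level": lv,
                "test": "chi_square",
                "user_n": table[0][i],
                "user_pct": 100 * table[0][i] / max(1, len(users)),
                "nonuser_n": table[1][i],
                "nonuser_pct": 100 * table[1][i] / max(1, len(nonusers)),
                "statistic": statistic, "p": p,
            })
    oi_cols = [c for c in users.columns if c.startswith("oi_")]
    for col in oi_cols:
        table = [
            [int((users[col] == 0).sum()), int((users[col] == 1).sum())],
            [int((nonusers[col] == 0).sum()), int((nonusers[col] == 1).sum())],
        ]
        try:
            statistic, _, p = chi_square_test(table)
        except DataError:
            statistic, p = np.nan, np.nan
        rows.append({
            "sample": sample, "characteristic": col, "level": "yes",
            "test": "chi_square",
            "user_n": table[0][1],
            "user_pct": 100 * table[0][1] / max(1, len(users)),
            "nonuser_n": table[1][1],
            "nonuser_pct": 100 * table[1][1] / max(1, len(nonusers)),
            "statistic": statistic, "p": p,
        })
    for col in _CONTINUOUS:
        try:
            statistic, _, p = t_test_unpaired(users[col], nonusers[col])
        except DataError:
            statistic, p = np.nan, np.nan
        rows.append({
            "sample": sample, "characteristic": col, "level": "",
            "test": "t_test",
            "user_mean": float(users[col].mean()),
            "user_sd": float(users[col].std(ddof=1)),
            "nonuser_mean": float(nonusers[col].mean()),
            "nonuser_sd": float(nonusers[col].std(ddof=1)),
            "statistic": statistic, "p": p,
        })
    return rows


def baseline_table(
    cohort: pd.DataFrame, matched: "psm.MatchedSet | None" = None
) -> pd.DataFrame:
    """Baseline characteristics with the appropriate two-group test per
    row, for the full (pre-match) cohort and, when a matched set is given,
    the matched sample."""
    users = cohort.loc[cohort["chm_user"] == 1]
    nonusers = cohort.loc[cohort["chm_user"] == 0]
    rows = _arm_rows(users, nonusers, "included")
    if matched is not None and matched.triples:
        by_id = cohort.set_index("patient_id")
        mu = by_id.loc[matched.user_ids].reset_index()
        mc = by_id.loc[matched.control_ids].reset_index()
        rows += _arm_rows(mu, mc, "matched")
    df = pd.DataFrame(rows)
    df["p_rendered"] = df["p"].map(
        lambda v: "" if pd.isna(v) else format_p(float(v)))
    return df


# ---------------------------------------------------------------------------
# Pipeline


@dataclass
class PipelineConfig:
    outdir: str = "out"
    data_dir: str | None = None          # read an existing bundle instead
    generator: GeneratorConfig | None = None
    psm_k: int = 2
    psm_caliper_sd_mult: float = 0.2
    outcomes: tuple[str, ...] = ("all_cause", "infect_circ")
    subgroup: str | None = None
    adjust_interval: bool = False
    arm_top_k: int = 5
    arm_node_min_freq: int = 1
    arm_edge_min_support_pct: float = 0.0
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            doc = yaml.safe_load(fh) or {}
        gen = doc.pop("generator", None)
        cfg = cls(**doc)
        if gen is not None:
            cfg.generator = GeneratorConfig(**gen)
        if cfg.generator is not None:
            cfg.generator.seed = cfg.seed
        return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run generate -> build-cohort -> match -> baseline -> survival ->
    rule/network mining, writing every artifact and a checksum manifest.

    Fully deterministic given the seed.  Any stage failure removes the
    partially written outputs and re-raises with the stage name.
    """
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "configure"

    def _emit(path: Path) -> Path:
        written.append(path)
        return path

    try:
        stage = "generate"
        if config.generator is not None:
            gen = config.generator
            gen.seed = config.seed
            bundle = generate_bundle(gen)
            files = write_bundle(bundle, outdir / "data")
            written.extend(Path(p) for p in files.values())
        elif config.data_dir:
            bundle = read_bundle(config.data_dir)
        else:
            raise ConfigurationError(
                "config needs either a generator section or data_dir")

        stage = "build-cohort"
        cohort, tally = cohort_builder.build_cohort(bundle)
        cohort_builder.write_cohort(cohort, _emit(outdir / "cohort.csv"))
        cohort_builder.write_exclusions(tally, _emit(outdir / "exclusions.json"))

        stage = "match"
        model = psm.fit_logistic_ps(cohort)
        matched = psm.match_1_to_k(
            model, cohort.set_index("patient_id")["chm_user"],
            k=config.psm_k, caliper_sd_mult=config.psm_caliper_sd_mult,
            seed=config.seed,
        )
        matched.to_frame().to_csv(_emit(outdir / "matched.csv"), index=False)
        psm.balance_table(matched, cohort).to_csv(
            _emit(outdir / "balance.csv"), index=False)

        stage = "baseline"
        baseline_table(cohort, matched).to_csv(
            _emit(outdir / "baseline.csv"), index=False)

        stage = "survival"
        extra = ("interval_days",) if config.adjust_interval else ()
        for outcome in config.outcomes:
            res = survival_stats.run_mortality_analysis(
                cohort, matched, outcome=outcome,
                extra_covariates=extra, subgroup=config.subgroup,
            )
            for label, curve in res.curves.items():
                curve.to_frame().to_csv(
                    _emit(outdir / f"km_{outcome}_{label}.csv"), index=False)
            tab = []
            for block, fit in res.crude.items():
                s = fit.summary()
                s.insert(0, "model", f"crude_{block}")
                tab.append(s)
            s = res.adjusted.summary()
            s.insert(0, "model", "adjusted")
            tab.append(s)
            models = pd.concat(tab, ignore_index=True)
            models["p_rendered"] = models["p"].map(format_p)
            models.to_csv(_emit(outdir / f"cox_{outcome}.csv"), index=False)
            summary = {
                "outcome": outcome,
                "n": res.n, "n_events": res.n_events,
                "logrank_chi2": res.logrank_chi2,
                "logrank_p": res.logrank_p,
                "adjusted_chm_hr": res.adjusted.hr["chm_user"],
                "adjusted_chm_ci": [res.adjusted.ci_low["chm_user"],
                                    res.adjusted.ci_high["chm_user"]],
            }
            _emit(outdir / f"survival_{outcome}.json").write_text(
                json.dumps(summary, indent=2), encoding="utf-8")

        stage = "arm"
        chm = bundle.prescriptions.loc[bundle.prescriptions["class"] == "CHM"]
        ts = arm_network.build_transactions(chm)
        rules = arm_network.top_rules(ts, k=config.arm_top_k)
        arm_network.rules_table(rules, chm).to_csv(
            _emit(outdir / "rules.csv"), index=False)
        graph = arm_network.build_graph(
            rules, chm, node_min_freq=config.arm_node_min_freq,
            edge_min_support_pct=config.arm_edge_min_support_pct,
        )
        graph.to_graphml(_emit(outdir / "network.graphml"))
        graph.to_edge_list_json(_emit(outdir / "network.json"))

        stage = "manifest"
        manifest = {
            "seed": config.seed,
            "n_cohort": int(len(cohort)),
            "exclusions": tally,
            "n_matched_users": len(matched.triples),
            "files": {
                str(p.relative_to(outdir)): _sha256(p)
                for p in sorted(written) if p.exists()
            },
        }
        (outdir / "manifest.json").write_text(
            json.dumps(manifest, indent=2), encoding="utf-8")
        return manifest
    except Exception as exc:
        for p in written:
            try:
                if p.exists():
                    p.unlink()
            except OSError:
                pass
        raise type(exc)(f"pipeline stage {stage!r} failed: {exc}") from exc


def plot_km(curves: dict, path, title: str = "Cumulative mortality") -> None:
    """Static cumulative-incidence (1 - S) step plot for two arms."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, curve in curves.items():
        t = np.concatenate([[0.0], curve.event_times])
        s = np.concatenate([[1.0], curve.survival])
        ax.step(t / 365.25, 1.0 - s, where="post", label=label)
    ax.set_xlabel("years since index date")
    ax.set_ylabel("cumulative incidence")
    ax.set_title(title)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
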