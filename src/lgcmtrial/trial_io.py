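"""Reading/writing trial tables, run configuration, and the simulate->fit->report pipeline.

CSV dialect: comma-separated UTF-8, missing values as empty cells.  A wide file
(one row per participant; the analysis input) and a long file (one row per
participant-wave; for plotting) are both supported.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .effect_stats import (
    GroupSummary,
    change_correlations,
    change_scores,
    chisq_2x2,
    cohen_d_cross,
    format_correlations,
    smd_change,
    two_sample_t,
)
from .inference import ModelSpec, fit_ml, sample_posterior
from .measures import classify_depression, classify_social_anxiety, time_basis
from .synthetic import (
    OUTCOME_NAMES,
    WIDE_COLUMNS,
    GeneratorConfig,
    TrialDataset,
    generate,
)

log = logging.getLogger("lgcmtrial")

__all__ = [
    "read_trial_csv",
    "write_trial_csv",
    "RunConfig",
    "run_pipeline",
    "load_generator_config",
    "plot_trajectories",
]

_INT_COLUMNS = {"pid", "female", "bonus_months", "compensation_jpy"} | {
    f"{b}_w{w}" for b in ("bell", "custom") for w in (1, 2, 3, 4)
}


def write_trial_csv(dataset: TrialDataset, path) -> None:
    """Write the wide participant table; missing outcomes become empty cells."""
    dataset.wide.to_csv(path, index=False)


def read_trial_csv(path) -> TrialDataset:
    """Load a wide trial CSV back into a typed dataset.

    Unknown columns, non-numeric cells in numeric columns, and an empty data
    section are all reported as errors (with the offending names / row index).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in df.columns if c not in WIDE_COLUMNS]
    if unknown:
        raise ValueError(f"unknown columns in {path}: {unknown}")
    missing = [c for c in WIDE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns in {path}: {missing}")
    if len(df) == 0:
        raise ValueError(f"{path} has a header but no data rows")

    out = {}
    for col in WIDE_COLUMNS:
        raw = df[col]
        if col == "arm":
            bad = ~raw.isin(["exp", "wait"])
            if bad.any():
                raise ValueError(
                    f"column 'arm' row {int(np.nonzero(bad.to_numpy())[0][0])}: "
                    f"expected 'exp' or 'wait', got {raw[bad].iloc[0]!r}"
                )
            out[col] = raw.to_numpy()
            continue
        vals = pd.to_numeric(raw.where(raw != ""), errors="coerce")
        bad = vals.isna() & (raw != "")
        if bad.any():
            row = int(np.nonzero(bad.to_numpy())[0][0])
            raise ValueError(f"column {col!r} row {row}: non-numeric value {raw.iloc[row]!r}")
        if col in _INT_COLUMNS:
            if vals.isna().any():
                raise ValueError(f"column {col!r} may not contain missing values")
            out[col] = vals.astype(np.int64).to_numpy()
        else:
            out[col] = vals.to_numpy(dtype=float)
    return TrialDataset(pd.DataFrame(out, columns=list(WIDE_COLUMNS)))


def load_generator_config(path=None) -> GeneratorConfig:
    """Read a generator configuration from YAML (missing keys take defaults).

    With no path, loads the packaged study-conditions file
    (``lgcmtrial/config/default_trial.yaml``).
    """
    if path is None:
        from importlib import resources

        text = resources.files("lgcmtrial").joinpath("config/default_trial.yaml").read_text()
        raw = yaml.safe_load(text)
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
    return GeneratorConfig.from_dict(raw)


@dataclass
class RunConfig:
    """One end-to-end pipeline run.

    ``subgroup`` restricts the analysis sample by baseline clinical status:
    ``"depressed"`` keeps baseline QIDS >= 6, ``"social_anxiety"`` keeps
    baseline adjusted physical-community LSAS >= 30, ``None`` keeps everyone.
    """

    out_dir: str = "report"
    data_path: str | None = None          # load instead of simulating
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    outcomes: tuple[str, ...] = ("qids", "lsas_v", "lsas_p", "bell_log2", "custom_log2")
    months: tuple[float, ...] = (0.0, 1.0, 2.0, 3.0)
    estimator: str = "ml"                 # "ml" or "mcmc"
    mcmc_iter: int = 1000
    mcmc_chains: int = 2
    subgroup: str | None = None
    seed: int = 0
    make_plot: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "generator" in raw:
            raw["generator"] = GeneratorConfig.from_dict(raw["generator"])
        for key in ("outcomes", "months"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def config_hash(self) -> str:
        payload = asdict(self)
        payload["generator"] = self.generator.to_dict()
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _subgroup_mask(dataset: TrialDataset, rule: str | None) -> np.ndarray:
    base_qids = dataset.wide["qids_w1"].to_numpy(dtype=float)
    base_lsas = dataset.wide["lsas_p_w1"].to_numpy(dtype=float)
    if rule is None:
        return np.ones(len(dataset), dtype=bool)
    if rule == "depressed":
        return np.array([
            (not np.isnan(v)) and classify_depression(float(np.clip(v, 0, 27)))
            for v in base_qids
        ])
    if rule == "social_anxiety":
        return np.array([
            (not np.isnan(v)) and classify_social_anxiety(max(float(v), 0.0))
            for v in base_lsas
        ])
    raise ValueError(f"unknown subgroup rule {rule!r}")


def baseline_table(dataset: TrialDataset) -> pd.DataFrame:
    """Arm comparison at baseline: t/d for continuous rows, chi-square/phi for female."""
    wide = dataset.wide
    exp = wide[wide["arm"] == "exp"]
    wait = wide[wide["arm"] == "wait"]
    rows = []

    def cont_row(label, col, welch=False):
        a, b = exp[col].dropna(), wait[col].dropna()
        t = two_sample_t(a, b, welch=welch)
        d = cohen_d_cross(
            GroupSummary(len(a), a.mean(), a.std(ddof=1)),
            GroupSummary(len(b), b.mean(), b.std(ddof=1)),
        )
        rows.append({
            "variable": label,
            "exp": f"{a.mean():.3f} ({a.std(ddof=1):.3f})",
            "wait": f"{b.mean():.3f} ({b.std(ddof=1):.3f})",
            "statistic": f"t={t.t:.3f} (df={t.df:.1f})",
            "pvalue": t.pvalue, "effect_size": d, "effect_kind": "cohen_d",
        })

    cont_row("age", "age", welch=True)
    n_f = [int(exp["female"].sum()), int(wait["female"].sum())]
    tab = [[n_f[0], len(exp) - n_f[0]], [n_f[1], len(wait) - n_f[1]]]
    c = chisq_2x2(tab)
    rows.append({
        "variable": "female",
        "exp": f"{n_f[0]} ({n_f[0] / len(exp):.3f})",
        "wait": f"{n_f[1]} ({n_f[1] / len(wait):.3f})",
        "statistic": f"chi2={c.chi2:.3f} (df={c.df})",
        "pvalue": c.pvalue, "effect_size": c.phi, "effect_kind": "phi",
    })
    for label, col in (
        ("depressive symptoms", "qids_w1"),
        ("social anxiety (virtual)", "lsas_v_w1"),
        ("social anxiety (physical)", "lsas_p_w1"),
    ):
        cont_row(label, col)
    return pd.DataFrame(rows)


def effects_table(dataset: TrialDataset) -> pd.DataFrame:
    """Change-score SMD per outcome plus per-arm per-wave mean (SD) cells."""
    ch = change_scores(dataset.wide)
    rows = []
    for outcome in ("qids", "lsas_v", "lsas_p", "bell_log2", "custom_log2"):
        diff_col = {
            "qids": "diff_qids", "lsas_v": "diff_lsas_v", "lsas_p": "diff_lsas_p",
            "bell_log2": "diff_bell_log2", "custom_log2": "diff_custom_log2",
        }[outcome]
        smd = smd_change(
            ch.loc[ch["arm"] == "exp", diff_col],
            ch.loc[ch["arm"] == "wait", diff_col],
        )
        row = {"outcome": outcome, "smd_change": smd}
        y = dataset.outcome_matrix(outcome)
        arm = dataset.wide["arm"].to_numpy()
        for label in ("exp", "wait"):
            sub = y[arm == label]
            for w in range(y.shape[1]):
                col = sub[:, w]
                col = col[~np.isnan(col)]
                row[f"{label}_w{w + 1}"] = f"{col.mean():.2f} ({col.std(ddof=1):.2f})"
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Simulate (or load), fit each requested outcome, compute effect sizes, write a report.

    The report directory receives a baseline comparison table, one fit summary
    per outcome, the change-score SMD table, per-arm correlation matrices and
    a machine-readable ``report.json`` embedding the seed, config hash,
    package version and per-stage wall times.  Reruns with identical inputs
    produce identical CSV/JSON payloads.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    report: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": __version__,
    }

    def stage(name):
        log.info("stage %s starting (seed=%d)", name, config.seed)
        return time.perf_counter()

    t0 = stage("data")
    try:
        if config.data_path is not None:
            dataset = read_trial_csv(config.data_path)
        else:
            dataset = generate(config.generator, seed=config.seed)
            write_trial_csv(dataset, out_dir / "trial_wide.csv")
            dataset.to_long().to_csv(out_dir / "trial_long.csv", index=False)
    except Exception as err:
        raise RuntimeError(f"pipeline stage 'data' failed: {err}") from err
    timings["data"] = time.perf_counter() - t0

    mask = _subgroup_mask(dataset, config.subgroup)
    analysed = dataset.subset(mask) if config.subgroup else dataset
    report["n_total"] = len(dataset)
    report["n_analysed"] = len(analysed)
    report["n_exp"] = analysed.n_exp
    report["n_wait"] = analysed.n_wait
    report["subgroup"] = config.subgroup

    t0 = stage("baseline")
    base = baseline_table(analysed)
    base.to_csv(out_dir / "baseline_table.csv", index=False)
    report["baseline"] = base.to_dict(orient="records")
    timings["baseline"] = time.perf_counter() - t0

    basis = time_basis(config.months)
    cov = analysed.covariate_matrix()
    report["fits"] = {}
    for outcome in config.outcomes:
        t0 = stage(f"fit:{outcome}")
        try:
            y = analysed.outcome_matrix(outcome)
            fit = fit_ml(y, cov, basis)
            entry = {
                "estimator": "ml",
                "loglik": fit.loglik,
                "converged": fit.converged,
                "coefficients": fit.summary_rows(),
            }
            if config.estimator == "mcmc":
                post = sample_posterior(
                    y, cov, basis, n_chains=config.mcmc_chains,
                    n_iter=config.mcmc_iter, seed=config.seed,
                )
                w, l = post.waic(), post.loo()
                entry["mcmc"] = {
                    "rhat": post.rhat,
                    "waic": {"elpd": w.elpd_waic, "p": w.p_waic, "deviance": w.deviance},
                    "loo": {"elpd": l.elpd_loo, "p": l.p_loo, "deviance": l.deviance},
                }
        except Exception as err:
            raise RuntimeError(f"pipeline stage 'fit:{outcome}' failed: {err}") from err
        report["fits"][outcome] = entry
        pd.DataFrame(entry["coefficients"]).to_csv(out_dir / f"fit_{outcome}.csv", index=False)
        timings[f"fit:{outcome}"] = time.perf_counter() - t0

    t0 = stage("effects")
    eff = effects_table(analysed)
    eff.to_csv(out_dir / "effects_table.csv", index=False)
    report["smd_change"] = dict(zip(eff["outcome"], eff["smd_change"]))
    for arm in ("exp", "wait"):
        corr = change_correlations(analysed.wide, arm)
        corr.r.to_csv(out_dir / f"correlations_{arm}.csv")
        format_correlations(corr).to_csv(out_dir / f"correlations_{arm}_starred.csv")
    timings["effects"] = time.perf_counter() - t0

    if config.make_plot:
        t0 = stage("plot")
        plot_trajectories(analysed, config.outcomes[0], out_dir / "trajectories.png")
        timings["plot"] = time.perf_counter() - t0

    report["timings_s"] = {k: round(v, 4) for k, v in timings.items()}
    payload = {k: v for k, v in report.items() if k != "timings_s"}
    with open(out_dir / "report.json", "w") as fh:
        json.dump({**payload, "timings_s": report["timings_s"]}, fh, indent=2, default=float)
    for name, dt in timings.items():
        log.info("stage %-14s %8.3fs", name, dt)
    return report


def plot_trajectories(dataset: TrialDataset, outcome: str, path) -> None:
    """Per-arm mean trajectory with a 95% CI band (basic diagnostic plot)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = dataset.outcome_matrix(outcome)
    arm = dataset.wide["arm"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, color in (("exp", "C0"), ("wait", "C1")):
        sub = y[arm == label]
        mean = np.nanmean(sub, axis=0)
        se = np.nanstd(sub, axis=0, ddof=1) / np.sqrt((~np.isnan(sub)).sum(axis=0))
        waves = np.arange(1, y.shape[1] + 1)
        ax.plot(waves, mean, marker="o", color=color, label=label)
        ax.fill_between(waves, mean - 1.96 * se, mean + 1.96 * se, alpha=0.2, color=color)
    ax.set_xlabel("wave")
    ax.set_ylabel(outcome)
    ax.set_xticks(np.arange(1, y.shape[1] + 1))
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
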