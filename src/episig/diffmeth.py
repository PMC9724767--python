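"""Episignature derivation: moderated t-statistics, FDR control,
effect-size filtering and correlation pruning.

The per-probe test is an empirical-Bayes moderated two-sample t: the
per-probe pooled variance :math:`s_g^2` (with :math:`d_g = n_1 + n_2 - 2`
residual degrees of freedom) is shrunk toward a prior variance
:math:`s_0^2` with prior degrees of freedom :math:`d_0`,

.. math::

    \\tilde s^2 = \\frac{d_0 s_0^2 + d_g s_g^2}{d_0 + d_g}, \\qquad
    t = \\frac{\\bar x_1 - \\bar x_2}{\\tilde s \\sqrt{1/n_1 + 1/n_2}},

with a two-sided p-value from a t distribution on :math:`d_0 + d_g`
degrees of freedom (standard normal when :math:`d_0 = \\infty`).  The
prior :math:`(d_0, s_0^2)` is fit by matching the first two moments of the
log sample variances to a scaled inverse-chi-square distribution, the
standard variance-shrinkage scheme for array data.

Statistics run on M-values; effect sizes (``delta_beta``) are reported on
the beta scale.  Selected probes are ranked by ``|t| * |delta_beta|`` and
greedily pruned so no two retained probes are correlated above ``prune_r``
across the training samples — the retained set is "independent" in that
operational sense.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import special, stats
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted
from statsmodels.stats.multitest import multipletests

from . import preprocess
from .preprocess import QCConfig


@dataclass(frozen=True)
class EBayesPrior:
    """Scaled inverse-chi-square variance prior: d0 degrees of freedom,
    s0_sq prior variance.  d0 = inf means no excess dispersion beyond
    chi-square sampling noise (all true variances equal s0_sq)."""

    d0: float
    s0_sq: float

    def __post_init__(self) -> None:
        if self.s0_sq <= 0:
            raise ValueError("s0_sq must be positive")
        if self.d0 < 0:
            raise ValueError("d0 must be nonnegative")


@dataclass(frozen=True)
class SelectConfig:
    """Probe selection thresholds.

    alpha : BH-adjusted p-value cutoff (default 0.01).
    min_abs_delta_beta : minimum absolute beta-scale effect (default 0.10).
    max_probes : cap on the ranked list before pruning (default 1000).
    prune_r : absolute Pearson correlation above which a lower-ranked
        probe is dropped (default 0.90).
    """

    alpha: float = 0.01
    min_abs_delta_beta: float = 0.10
    max_probes: int = 1000
    prune_r: float = 0.90

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 <= self.min_abs_delta_beta <= 1:
            raise ValueError("min_abs_delta_beta must be in [0, 1]")
        if self.max_probes < 1:
            raise ValueError("max_probes must be >= 1")
        if not 0 < self.prune_r <= 1:
            raise ValueError("prune_r must be in (0, 1]")


@dataclass
class EpiSignature:
    """A derived episignature: ranked probe statistics plus provenance."""

    probes: pd.DataFrame  # columns: probe_id, delta_beta, t_moderated, p_value, p_adjusted, rank
    provenance: dict = field(default_factory=dict)

    @property
    def probe_ids(self) -> list[str]:
        return self.probes["probe_id"].tolist()

    def __len__(self) -> int:
        return len(self.probes)


# ---------------------------------------------------------------------------
# empirical-Bayes prior


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 by Newton iteration."""
    if y <= 0:
        raise ValueError("trigamma inverse requires y > 0")
    if y > 1e7:
        return 1.0 / math.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(60):
        tri = special.polygamma(1, x)
        step = (tri - y) / special.polygamma(2, x)
        x -= step
        if x <= 0:
            x = 1e-8
        if abs(step) < 1e-12 * (1 + abs(x)):
            break
    return float(x)


def estimate_prior(sample_variances, df_residual: int) -> EBayesPrior:
    """Fit (d0, s0_sq) by moment-matching the log sample variances.

    Under the model, ``s_g^2 / s0^2`` follows an F(df_residual, d0)
    distribution; the mean and variance of ``log s_g^2`` then determine
    (d0, s0_sq) in closed form via digamma/trigamma functions.  When the
    observed dispersion of log variances does not exceed what chi-square
    sampling alone explains, d0 is infinite.
    """
    v = np.asarray(sample_variances, dtype=float)
    if len(v) < 10:
        raise ValueError("need at least 10 probes to estimate the prior")
    if df_residual < 1:
        raise ValueError("df_residual must be >= 1")
    if np.all(v == 0):
        raise ValueError("all sample variances are zero; degenerate data")
    if np.any(v < 0):
        raise ValueError("negative sample variance")
    pos = v[v > 0]
    if len(pos) < len(v):
        warnings.warn(
            f"{len(v) - len(pos)} zero variances excluded from prior fit"
        )

    if np.all(pos == pos[0]):
        # identical variances: no dispersion at all, not even chi-square
        # sampling noise -> infinite prior df at the common value
        return EBayesPrior(d0=math.inf, s0_sq=float(pos[0]))

    half_df = df_residual / 2.0
    e = np.log(pos) - special.digamma(half_df) + math.log(half_df)
    e_mean = float(np.mean(e))
    e_var = float(np.var(e, ddof=1)) - float(special.polygamma(1, half_df))
    if e_var <= 0:
        return EBayesPrior(d0=math.inf, s0_sq=math.exp(e_mean))
    d0 = 2.0 * _trigamma_inverse(e_var)
    s0_sq = math.exp(
        e_mean + special.digamma(d0 / 2.0) - math.log(d0 / 2.0)
    )
    return EBayesPrior(d0=d0, s0_sq=s0_sq)


# ---------------------------------------------------------------------------
# moderated t


def moderated_t(case_values, control_values, prior: EBayesPrior) -> pd.DataFrame:
    """Moderated two-sample t per probe.

    ``case_values`` and ``control_values`` are probes x samples arrays
    (1-D input is treated as a single probe).  Returns a frame with
    columns ``delta`` (mean difference on the input scale),
    ``t_moderated`` and two-sided ``p_value``.
    """
    case = np.atleast_2d(np.asarray(case_values, dtype=float))
    control = np.atleast_2d(np.asarray(control_values, dtype=float))
    n1, n2 = case.shape[1], control.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 samples per group")

    mean1 = case.mean(axis=1)
    mean2 = control.mean(axis=1)
    diff = mean1 - mean2
    dg = n1 + n2 - 2
    pooled = ((n1 - 1) * case.var(axis=1, ddof=1)
              + (n2 - 1) * control.var(axis=1, ddof=1)) / dg

    if math.isinf(prior.d0):
        s2_post = np.full_like(pooled, prior.s0_sq)
        df_total = math.inf
    else:
        s2_post = (prior.d0 * prior.s0_sq + dg * pooled) / (prior.d0 + dg)
        df_total = prior.d0 + dg

    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    t = np.zeros_like(diff)
    p = np.ones_like(diff)
    ok = se > 0
    t[ok] = diff[ok] / se[ok]
    if math.isinf(df_total):
        p[ok] = 2.0 * stats.norm.sf(np.abs(t[ok]))
    else:
        p[ok] = 2.0 * stats.t.sf(np.abs(t[ok]), df_total)
    degenerate = ~ok & (diff != 0)
    if degenerate.any():
        warnings.warn(
            f"{int(degenerate.sum())} probes have zero posterior variance "
            "with nonzero mean difference; p set to 0"
        )
        t[degenerate] = np.sign(diff[degenerate]) * np.inf
        p[degenerate] = 0.0
    return pd.DataFrame({"delta": diff, "t_moderated": t, "p_value": p})


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# selection and pruning


def select_probes(stats_frame: pd.DataFrame, cfg: SelectConfig | None = None) -> pd.DataFrame:
    """Filter by adjusted p and effect size, rank, and truncate.

    Keeps probes with ``p_adjusted < alpha`` and
    ``|delta_beta| >= min_abs_delta_beta``; ranks by
    ``|t_moderated| * |delta_beta|`` descending with probe_id as the tie
    break; truncates to ``max_probes``.  Empty results are allowed.
    """
    cfg = cfg or SelectConfig()
    kept = stats_frame[
        (stats_frame["p_adjusted"] < cfg.alpha)
        & (stats_frame["delta_beta"].abs() >= cfg.min_abs_delta_beta)
    ].copy()
    kept["_score"] = kept["t_moderated"].abs() * kept["delta_beta"].abs()
    kept = kept.sort_values(
        ["_score", "probe_id"], ascending=[False, True], kind="mergesort"
    ).drop(columns="_score")
    kept = kept.head(cfg.max_probes).reset_index(drop=True)
    kept["rank"] = np.arange(1, len(kept) + 1)
    return kept


def prune_correlated(
    selected: pd.DataFrame,
    beta_training: pd.DataFrame,
    prune_r: float = 0.90,
    groups=None,
) -> pd.DataFrame:
    """Greedy rank-order pruning of correlated probes.

    Walks the ranked list top-down and keeps a probe iff its absolute
    Pearson correlation with every already-kept probe (beta scale, across
    training samples) stays below ``prune_r``.  When ``groups`` (a
    per-sample label array, column order) is given, each probe is centered
    within each group first, so the correlation measures redundancy beyond
    the case/control effect — two probes that co-vary only because both
    respond to disease status are not redundant in that sense, whereas
    duplicated or co-regulated probes still correlate at 1 within groups.
    A probe with zero variance in the training samples has undefined
    correlation; it is treated as correlation 0 (kept-eligible) with a
    warning.
    """
    if selected.empty:
        out = selected.copy()
        out["rank"] = np.arange(1, len(out) + 1)
        return out
    probe_ids = selected["probe_id"].tolist()
    missing = [p for p in probe_ids if p not in beta_training.index]
    if missing:
        raise ValueError(f"selected probes absent from training matrix: {missing[:5]}")

    values = beta_training.loc[probe_ids].to_numpy(dtype=float)
    if groups is not None:
        groups = np.asarray(groups)
        if len(groups) != values.shape[1]:
            raise ValueError("groups length must match training sample count")
        values = values.copy()
        for g in np.unique(groups):
            cols = groups == g
            values[:, cols] -= values[:, cols].mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0)
    zero_var = sd == 0
    if zero_var.any():
        warnings.warn(
            f"{int(zero_var.sum())} selected probes have zero variance in "
            "training samples; treated as uncorrelated"
        )
    centered = values - values.mean(axis=1, keepdims=True)
    n_samples = values.shape[1]
    safe_sd = np.where(zero_var, 1.0, sd)

    kept_rows: list[int] = []
    for i in range(len(probe_ids)):
        ok = True
        for j in kept_rows:
            if zero_var[i] or zero_var[j]:
                continue
            r = (centered[i] @ centered[j]) / (n_samples * safe_sd[i] * safe_sd[j])
            if abs(r) >= prune_r:
                ok = False
                break
        if ok:
            kept_rows.append(i)

    out = selected.iloc[kept_rows].reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


# ---------------------------------------------------------------------------
# full derivation


def compute_probe_stats(
    beta: pd.DataFrame,
    case_ids,
    control_ids,
    epsilon: float = 0.01,
) -> tuple[pd.DataFrame, EBayesPrior]:
    """Per-probe moderated statistics for a case/control contrast.

    Returns a frame (probe_id, delta_beta, t_moderated, p_value,
    p_adjusted) and the fitted variance prior.  The test runs on
    M-values; delta_beta is computed on the beta scale.
    """
    case_ids, control_ids = list(case_ids), list(control_ids)
    m = preprocess.beta_to_m(beta, epsilon)
    case_m = m.loc[:, case_ids].to_numpy()
    control_m = m.loc[:, control_ids].to_numpy()
    dg = len(case_ids) + len(control_ids) - 2
    pooled = ((len(case_ids) - 1) * case_m.var(axis=1, ddof=1)
              + (len(control_ids) - 1) * control_m.var(axis=1, ddof=1)) / dg
    prior = estimate_prior(pooled, dg)
    result = moderated_t(case_m, control_m, prior)
    delta_beta = (beta.loc[:, case_ids].mean(axis=1)
                  - beta.loc[:, control_ids].mean(axis=1))
    frame = pd.DataFrame(
        {
            "probe_id": beta.index.astype(str),
            "delta_beta": delta_beta.to_numpy(),
            "t_moderated": result["t_moderated"].to_numpy(),
            "p_value": result["p_value"].to_numpy(),
        }
    )
    frame["p_adjusted"] = bh_adjust(frame["p_value"].to_numpy())
    return frame, prior


def derive_signature(
    beta: pd.DataFrame,
    sheet: pd.DataFrame,
    case_ids,
    control_ids,
    cfg: SelectConfig | None = None,
    qc_cfg: QCConfig | None = None,
    manifest: pd.DataFrame | None = None,
) -> EpiSignature:
    """Derive an episignature from cases vs matched controls.

    Pipeline: QC filter -> impute (control medians) -> M-values ->
    variance-prior fit -> moderated t per probe -> BH adjustment ->
    p/effect filtering and ranking -> correlation pruning.  Provenance
    records configs and the probe count surviving each stage.
    """
    cfg = cfg or SelectConfig()
    qc_cfg = qc_cfg or QCConfig()
    case_ids, control_ids = list(case_ids), list(control_ids)
    if set(case_ids) & set(control_ids):
        raise ValueError("case and control ids overlap")
    for sid in case_ids + control_ids:
        if sid not in beta.columns:
            raise ValueError(f"sample {sid!r} absent from beta matrix")

    train = beta.loc[:, case_ids + control_ids]
    train, qc_report = preprocess.qc_filter(train, qc_cfg, manifest)
    train = preprocess.impute_missing(train, control_ids)

    stats_frame, prior = compute_probe_stats(train, case_ids, control_ids, qc_cfg.epsilon)
    selected = select_probes(stats_frame, cfg)
    groups = np.asarray(["case"] * len(case_ids) + ["control"] * len(control_ids))
    pruned = prune_correlated(selected, train, cfg.prune_r, groups=groups)

    provenance = {
        "case_ids": case_ids,
        "control_ids": control_ids,
        "select_config": asdict(cfg),
        "qc_config": asdict(qc_cfg),
        "prior": {"d0": prior.d0 if math.isfinite(prior.d0) else "inf",
                  "s0_sq": prior.s0_sq},
        "counts": {
            "probes_in": int(beta.shape[0]),
            "probes_after_qc": int(train.shape[0]),
            "probes_significant": int((stats_frame["p_adjusted"] < cfg.alpha).sum()),
            "probes_selected": int(len(selected)),
            "probes_pruned": int(len(pruned)),
        },
        "qc_summary": {k: qc_report[k] for k in ("n_probes_in", "n_probes_out", "n_removed")},
    }
    return EpiSignature(probes=pruned, provenance=provenance)


# ---------------------------------------------------------------------------
# estimator interface


class EpiSignatureSelector(BaseEstimator, TransformerMixin):
    """Feature selector deriving an episignature from a labelled cohort.

    Follows the scikit-learn transformer contract: ``fit(X, y)`` with
    ``X`` a samples x probes beta-value DataFrame and ``y`` binary labels
    (nonzero/truthy = case); ``transform(X)`` restricts ``X`` to the
    signature probes.

    Parameters mirror :class:`SelectConfig` plus the logit ``epsilon``.

    Attributes
    ----------
    signature_ : EpiSignature
        Ranked probe statistics with provenance.
    probe_ids_ : list of str
        Selected probe ids, rank order.
    prior_ : EBayesPrior
        Fitted variance prior.
    """

    def __init__(self, alpha: float = 0.01, min_abs_delta_beta: float = 0.10,
                 max_probes: int = 1000, prune_r: float = 0.90,
                 epsilon: float = 0.01):
        self.alpha = alpha
        self.min_abs_delta_beta = min_abs_delta_beta
        self.max_probes = max_probes
        self.prune_r = prune_r
        self.epsilon = epsilon

    def fit(self, X: pd.DataFrame, y):
        if not isinstance(X, pd.DataFrame):
            raise TypeError("X must be a samples x probes DataFrame")
        y = np.asarray(y)
        if len(y) != X.shape[0]:
            raise ValueError("y length must match number of samples")
        mask = y.astype(bool)
        if mask.all() or not mask.any():
            raise ValueError("need both case and control samples")
        beta = X.T  # probes x samples
        cfg = SelectConfig(alpha=self.alpha,
                           min_abs_delta_beta=self.min_abs_delta_beta,
                           max_probes=self.max_probes, prune_r=self.prune_r)
        qc_cfg = QCConfig(epsilon=self.epsilon)
        sheet = pd.DataFrame({"sample_id": X.index.astype(str)})
        self.signature_ = derive_signature(
            beta, sheet,
            case_ids=list(X.index[mask].astype(str)),
            control_ids=list(X.index[~mask].astype(str)),
            cfg=cfg, qc_cfg=qc_cfg,
        )
        self.probe_ids_ = self.signature_.probe_ids
        self.prior_ = EBayesPrior(
            d0=(math.inf if self.signature_.provenance["prior"]["d0"] == "inf"
                else self.signature_.provenance["prior"]["d0"]),
            s0_sq=self.signature_.provenance["prior"]["s0_sq"],
        )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        check_is_fitted(self, "probe_ids_")
        missing = [p for p in self.probe_ids_ if p not in X.columns]
        if missing:
            raise ValueError(f"signature probes absent from X: {missing[:5]}")
        return X.loc[:, self.probe_ids_]
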