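"""Beta/M-value conversion, probe QC and imputation.

Differential statistics downstream run on M-values, ``M = log2(b / (1 - b))``,
which stabilises the heteroskedastic variance of beta values near 0 and 1;
effect sizes are always reported back on the beta scale.  Betas are clamped
into ``[epsilon, 1 - epsilon]`` before the logit so boundary values stay
finite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class QCConfig:
    """Probe-level quality control settings.

    max_missing_fraction : drop probes missing in more than this fraction
        of samples (default 0.05).
    drop_zero_variance : drop probes constant across all samples.
    drop_sex_chromosomes : drop X/Y probes; requires a probe manifest.
    epsilon : logit clamp used by the beta -> M transform (default 0.01).
    """

    max_missing_fraction: float = 0.05
    drop_zero_variance: bool = True
    drop_sex_chromosomes: bool = False
    epsilon: float = 0.01

    def __post_init__(self) -> None:
        if not 0.0 <= self.max_missing_fraction <= 1.0:
            raise ValueError("max_missing_fraction must be in [0, 1]")
        if not 0.0 < self.epsilon < 0.5:
            raise ValueError("epsilon must be in (0, 0.5)")


def logit_clip(beta, epsilon: float = 0.01):
    """log2(b / (1 - b)) after clamping b into [epsilon, 1 - epsilon].

    Accepts scalars or arrays; NaN propagates.
    """
    if not 0.0 < epsilon < 0.5:
        raise ValueError("epsilon must be in (0, 0.5)")
    b = np.clip(np.asarray(beta, dtype=float), epsilon, 1.0 - epsilon)
    out = np.log2(b / (1.0 - b))
    if np.isscalar(beta) or np.ndim(beta) == 0:
        return float(out)
    return out


def inverse_logit(m):
    """Map an M-value back to a beta value: 2**m / (1 + 2**m)."""
    m = np.asarray(m, dtype=float)
    out = 1.0 / (1.0 + np.exp2(-m))
    if np.ndim(out) == 0:
        return float(out)
    return out


def beta_to_m(beta: pd.DataFrame, epsilon: float = 0.01) -> pd.DataFrame:
    """Elementwise logit transform of a beta matrix; ids and NaN preserved."""
    values = logit_clip(beta.to_numpy(dtype=float), epsilon)
    return pd.DataFrame(values, index=beta.index, columns=beta.columns)


def m_to_beta(m: pd.DataFrame) -> pd.DataFrame:
    values = inverse_logit(m.to_numpy(dtype=float))
    return pd.DataFrame(values, index=m.index, columns=m.columns)


def qc_filter(
    beta: pd.DataFrame,
    cfg: QCConfig | None = None,
    manifest: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Remove probes failing QC; return the filtered matrix and a report.

    The report lists every removed probe with its reason
    (``missing_fraction``, ``zero_variance`` or ``sex_chromosome``) plus
    summary counts.  Samples are never removed.  Idempotent.
    """
    cfg = cfg or QCConfig()
    removed: list[dict] = []
    keep = pd.Series(True, index=beta.index)

    values = beta.to_numpy(dtype=float)
    missing_frac = np.isnan(values).mean(axis=1)
    for probe, frac in zip(beta.index[missing_frac > cfg.max_missing_fraction],
                           missing_frac[missing_frac > cfg.max_missing_fraction]):
        removed.append({"probe_id": str(probe), "reason": "missing_fraction",
                        "detail": float(frac)})
        keep[probe] = False

    if cfg.drop_zero_variance:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            value_range = np.nanmax(values, axis=1) - np.nanmin(values, axis=1)
        zero_var = keep.to_numpy() & (value_range == 0)
        for probe in beta.index[zero_var]:
            removed.append({"probe_id": str(probe), "reason": "zero_variance"})
            keep[probe] = False

    if cfg.drop_sex_chromosomes:
        if manifest is None:
            raise ValueError("drop_sex_chromosomes requires a probe manifest")
        chrom = manifest.set_index("probe_id")["chromosome"]
        uncovered = beta.index.difference(chrom.index)
        if len(uncovered):
            raise ValueError(
                f"probe manifest does not cover probes {list(uncovered[:5])}"
            )
        sexchrom = chrom.reindex(beta.index).isin(["X", "Y", "chrX", "chrY"])
        for probe in beta.index[keep.to_numpy() & sexchrom.to_numpy()]:
            removed.append({"probe_id": str(probe), "reason": "sex_chromosome"})
            keep[probe] = False

    report = {
        "n_probes_in": int(beta.shape[0]),
        "n_probes_out": int(keep.sum()),
        "n_removed": len(removed),
        "removed": removed,
    }
    return beta.loc[keep], report


def impute_missing(beta: pd.DataFrame, reference_sample_ids) -> pd.DataFrame:
    """Replace missing cells by the per-probe median over reference samples.

    Reference samples are typically the controls, so imputed values never
    borrow case signal.  A probe with no non-missing reference value is an
    error.
    """
    reference_sample_ids = list(reference_sample_ids)
    missing_ref = [s for s in reference_sample_ids if s not in beta.columns]
    if missing_ref:
        raise ValueError(f"reference samples absent from matrix: {missing_ref[:5]}")
    if not beta.isna().any().any():
        return beta.copy()
    ref = beta.loc[:, reference_sample_ids].to_numpy(dtype=float)
    all_missing = np.isnan(ref).all(axis=1)
    if all_missing.any():
        probe = beta.index[all_missing][0]
        raise ValueError(f"probe {probe!r} entirely missing in reference samples")
    medians = np.nanmedian(ref, axis=1)
    out = beta.to_numpy(dtype=float).copy()
    rows, cols = np.nonzero(np.isnan(out))
    out[rows, cols] = medians[rows]
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)
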