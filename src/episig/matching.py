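"""Age- and sex-matched control selection.

Greedy per-case nearest-age matching without replacement: cases are walked
in input order and each receives the ``ratio`` sex-matching pool samples
with the smallest absolute age difference.  Ties are broken by a seeded
shuffle, then id order, making the selection reproducible and the match
table auditable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass(frozen=True)
class MatchConfig:
    ratio: int = 3                 # controls selected per case
    require_exact_sex: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


class MatchingError(ValueError):
    """Raised when the pool cannot supply matches for some case."""


def select_matched_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    cfg: MatchConfig | None = None,
) -> tuple[list[str], pd.DataFrame]:
    """Select ``ratio`` age/sex-matched controls per case from a pool.

    Parameters
    ----------
    cases, pool
        Sample-sheet subsets (columns ``sample_id``, ``age``, ``sex``).
        Must be disjoint on ``sample_id``.

    Returns
    -------
    (control_ids, match_table)
        ``control_ids`` in selection order; ``match_table`` has columns
        ``case_id, control_id, age_gap_years``.
    """
    cfg = cfg or MatchConfig()
    overlap = set(cases["sample_id"]) & set(pool["sample_id"])
    if overlap:
        raise MatchingError(f"pool overlaps cases: {sorted(overlap)[:5]}")

    rng = np.random.default_rng(cfg.seed)
    pool = pool.copy()
    # tie-break key: seeded shuffle rank, then id; stable across runs
    shuffle_rank = rng.permutation(len(pool))
    pool["_tie"] = shuffle_rank
    available = pool.set_index("sample_id")

    selected: list[str] = []
    rows: list[dict] = []
    for case in cases.itertuples(index=False):
        candidates = available
        if cfg.require_exact_sex:
            candidates = candidates[candidates["sex"] == case.sex]
        if len(candidates) < cfg.ratio:
            raise MatchingError(
                f"case {case.sample_id!r} ({case.sex}, age {case.age}): only "
                f"{len(candidates)} sex-matched pool samples left, need {cfg.ratio}"
            )
        gaps = (candidates["age"] - case.age).abs()
        order = pd.DataFrame(
            {"gap": gaps, "_tie": candidates["_tie"]}
        ).sort_values(["gap", "_tie"], kind="mergesort")
        chosen = order.index[: cfg.ratio]
        for ctrl in chosen:
            selected.append(str(ctrl))
            rows.append(
                {"case_id": case.sample_id, "control_id": str(ctrl),
                 "age_gap_years": float(order.loc[ctrl, "gap"])}
            )
        available = available.drop(index=chosen)

    return selected, pd.DataFrame(rows, columns=["case_id", "control_id", "age_gap_years"])
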