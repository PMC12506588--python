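"""Editing-site <-> splicing-event association.

Each editing site is paired with the nearest AS event *within its host gene*
(distance to the event's defining splice-site boundaries), and the per-sample
editing level is correlated with the event's PSI.  Pairs with |r| > 0.5 and
p < 0.05 are considered significantly associated.  Spearman rank correlation
is the default (exact permutation p for n <= 9, t approximation above);
Pearson is available via ``method``.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ValidationError
from .splicing import ASEvent

MIN_SAMPLES = 5


@dataclass
class ResAsPair:
    site_id: str
    event_id: str
    gene_id: str
    distance: int


def assign_nearest_event(
    site_id: str, pos: int, events_in_gene: list[ASEvent], gene_id: str = ""
) -> ResAsPair | None:
    """Nearest event by minimum absolute distance to any defining boundary.

    Ties break on (smaller event start, then lexicographic event_id).
    Returns None when the gene has no events.
    """
    best: tuple[int, int, str] | None = None
    best_ev: ASEvent | None = None
    for ev in events_in_gene:
        d = min(abs(pos - b) for b in ev.defining_boundaries())
        key = (d, min(ev.coords), ev.event_id)
        if best is None or key < best:
            best, best_ev = key, ev
    if best_ev is None:
        return None
    return ResAsPair(site_id, best_ev.event_id, gene_id or best_ev.gene_id,
                     best[0])


def _spearman_exact_p(x: np.ndarray, y: np.ndarray, rho_obs: float) -> float:
    """Exact two-sided permutation p for Spearman's rho at small n.

    Enumerates all n! orderings of one vector's ranks; requires tie-free
    ranks (callers fall back to the t approximation when ties are present).
    """
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    count = 0
    total = 0
    target = abs(rho_obs) - 1e-12
    for perm in permutations(range(n)):
        r = float(np.mean(rx[list(perm)] * ry))
        total += 1
        if abs(r) >= target:
            count += 1
    return count / total


def correlate(
    editing_levels: pd.Series | np.ndarray,
    psi: pd.Series | np.ndarray,
    method: str = "spearman",
) -> tuple[float, float, int]:
    """Correlate per-sample editing levels with PSI over shared, defined
    samples.  Returns (r, p, n_used); raises on < 5 usable samples or a
    constant vector."""
    x = np.asarray(editing_levels, float)
    y = np.asarray(psi, float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < MIN_SAMPLES:
        raise ValidationError(f"only {n} samples with both values (need >= 5)")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("constant input vector; correlation undefined")
    if method == "pearson":
        r, p = stats.pearsonr(x, y)
        return float(r), float(p), n
    if method != "spearman":
        raise ValidationError(f"unknown correlation method {method!r}")
    r, p = stats.spearmanr(x, y)
    has_ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if n <= 9 and not has_ties:
        p = _spearman_exact_p(x, y, float(r))
    return float(r), float(p), n


def correlate_pairs(
    pairs: list[ResAsPair],
    editing_levels: pd.DataFrame,
    psi: pd.DataFrame,
    design=None,
    method: str = "spearman",
    per_group: bool = False,
    group_a: str = "UIA",
    group_b: str = "RIA",
) -> pd.DataFrame:
    """Correlation statistics for assigned pairs, pooled and (optionally)
    within each group."""
    rows = []
    for pair in pairs:
        if pair.site_id not in editing_levels.index or (
            pair.event_id not in psi.index
        ):
            continue
        rec: dict = {
            "site_id": pair.site_id, "event_id": pair.event_id,
            "gene_id": pair.gene_id, "distance": pair.distance,
        }
        subsets = {"": editing_levels.columns}
        if per_group:
            if design is None:
                raise ValidationError("per_group correlation requires a design")
            subsets = {
                f"_{group_a}": [s for s in design.samples(group_a)
                                if s in editing_levels.columns],
                f"_{group_b}": [s for s in design.samples(group_b)
                                if s in editing_levels.columns],
            }
        for suffix, samples in subsets.items():
            try:
                r, p, n = correlate(
                    editing_levels.loc[pair.site_id, samples],
                    psi.loc[pair.event_id, samples],
                    method=method,
                )
                rec[f"r{suffix}"], rec[f"p{suffix}"], rec[f"n{suffix}"] = r, p, n
            except ValidationError:
                rec[f"r{suffix}"] = np.nan
                rec[f"p{suffix}"] = np.nan
                rec[f"n{suffix}"] = 0
        rows.append(rec)
    if not rows:
        return pd.DataFrame(
            columns=["site_id", "event_id", "gene_id", "distance", "r", "p", "n"]
        ).set_index(["site_id", "event_id"], drop=False)
    return pd.DataFrame(rows).set_index(["site_id", "event_id"], drop=False)


def filter_pairs(
    pairs: pd.DataFrame,
    min_abs_r: float = 0.5,
    alpha: float = 0.05,
    r_col: str = "r",
    p_col: str = "p",
) -> pd.DataFrame:
    """Significant pairs: |r| strictly > min_abs_r and p < alpha; adds a
    ``sign`` column (positive/negative correlation class)."""
    if pairs.empty:
        return pairs.assign(sign=pd.Series(dtype=str))
    keep = (pairs[r_col].abs() > min_abs_r) & (pairs[p_col] < alpha)
    keep &= pairs[r_col].notna()
    out = pairs[keep].copy()
    out["sign"] = np.where(out[r_col] > 0, "positive", "negative")
    return out
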