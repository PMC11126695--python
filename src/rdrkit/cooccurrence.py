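"""Checkerboard C-scores on cross-sectional cohorts, and agreement of
RDR dominance calls with external (e.g. in-vitro co-culture) calls.

The standardized C-score for taxa i and j over a set of habitats is

    c_ij = (r_i - S_ij)(r_j - S_ij) / (r_i + r_j - S_ij)

with r the per-taxon occupancy counts and S_ij the number of habitats
occupied by both.  Larger values indicate stronger segregation; nested
occurrence (S_ij equal to either r) gives zero.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .rdr_stats import PairSummary

logger = logging.getLogger(__name__)


@dataclass
class PresenceMatrix:
    """Binary sample x taxon occurrence matrix with derived counts."""

    bits: pd.DataFrame  # samples x taxa, values in {0, 1}

    def __post_init__(self) -> None:
        arr = self.bits.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("presence matrix must be binary")

    @classmethod
    def from_abundance(cls, values: pd.DataFrame) -> "PresenceMatrix":
        """Strict positive-abundance presence."""
        return cls(bits=(values > 0).astype(int))

    @property
    def taxon_ids(self) -> pd.Index:
        return self.bits.columns

    def occupancy(self) -> pd.Series:
        """r: number of samples each taxon occurs in."""
        return self.bits.sum(axis=0)

    def cooccurrence(self) -> pd.DataFrame:
        """S: symmetric pairwise co-occurrence counts (diagonal = r)."""
        arr = self.bits.to_numpy()
        s = arr.T @ arr
        return pd.DataFrame(s, index=self.bits.columns, columns=self.bits.columns)


def c_score(r_i: int, r_j: int, s_ij: int) -> float:
    """Stone-Roberts checkerboard score standardized by occupied habitats."""
    if not 0 <= s_ij <= min(r_i, r_j):
        raise ValueError(f"require 0 <= s_ij <= min(r_i, r_j); got "
                         f"r=({r_i}, {r_j}), s={s_ij}")
    denom = r_i + r_j - s_ij
    if denom <= 0:
        raise ValueError("C-score undefined: neither taxon occupies any sample")
    return (r_i - s_ij) * (r_j - s_ij) / denom


def all_pairwise_cscores(matrix: PresenceMatrix,
                         pairs: Sequence[tuple[str, str]] | None = None,
                         ) -> pd.DataFrame:
    """C-score for every (or each requested) unordered taxon pair.

    Pairs whose score is undefined (both taxa absent everywhere) are kept
    with a NaN score and ``defined=False``.
    """
    r = matrix.occupancy()
    s = matrix.cooccurrence()
    taxa = list(matrix.taxon_ids)
    if pairs is None:
        pairs = [(a, b) for a, b in itertools.combinations(sorted(taxa), 2)]
    else:
        known = set(taxa)
        for a, b in pairs:
            if a not in known or b not in known:
                raise KeyError(f"pair ({a!r}, {b!r}) references unknown taxon")
    rows = []
    for a, b in pairs:
        ri, rj, sij = int(r[a]), int(r[b]), int(s.loc[a, b])
        if ri + rj - sij <= 0:
            rows.append((a, b, np.nan, False))
        else:
            rows.append((a, b, c_score(ri, rj, sij), True))
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "c_score",
                                       "defined"])


def compare_pair_sets(cscores: pd.DataFrame,
                      differential_pairs: set[tuple[str, str]],
                      background_pairs: set[tuple[str, str]],
                      paired: bool = False) -> dict:
    """Compare C-score distributions of two disjoint pair sets.

    Defaults to the unpaired two-sided Mann-Whitney rank-sum test; the
    ``paired`` override runs a Wilcoxon signed-rank test on positionally
    matched sets of equal size.
    """
    if differential_pairs & background_pairs:
        raise ValueError("pair sets overlap")
    if not differential_pairs or not background_pairs:
        raise ValueError("both pair sets must be non-empty")
    indexed = cscores.set_index(["taxon_a", "taxon_b"])["c_score"]
    x = indexed.loc[sorted(differential_pairs)].dropna().to_numpy()
    y = indexed.loc[sorted(background_pairs)].dropna().to_numpy()
    if len(x) < 2 or len(y) < 2:
        logger.warning("compare_pair_sets: singleton set; rank test degenerate")
    if paired:
        if len(x) != len(y):
            raise ValueError("paired comparison requires equal-size sets")
        stat, p = stats.wilcoxon(x, y, alternative="two-sided")
    elif np.ptp(np.concatenate([x, y])) == 0:
        stat, p = np.nan, 1.0
    else:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    med_x, med_y = float(np.median(x)), float(np.median(y))
    direction = "none" if med_x == med_y else (
        "differential>background" if med_x > med_y else "background>differential")
    return {"statistic": float(stat), "p_value": float(p),
            "median_differential": med_x, "median_background": med_y,
            "n_differential": len(x), "n_background": len(y),
            "direction": direction}


def correlate_with_rdr(cscores: pd.DataFrame,
                       summaries: Sequence[PairSummary]) -> dict:
    """Spearman correlation of pair C-scores against |mean RDR|.

    Uses the display orientation in which the dominant partner is listed
    first, i.e. the magnitude of the mean RDR.  Restricted to
    differential pairs present in both tables; average ranks break ties.
    """
    indexed = cscores.set_index(["taxon_a", "taxon_b"])["c_score"]
    xs, ys = [], []
    for s in summaries:
        if not s.is_differential:
            continue
        key = (s.taxon_a, s.taxon_b)
        if key in indexed.index and np.isfinite(indexed.loc[key]):
            xs.append(abs(s.mean_rdr))
            ys.append(float(indexed.loc[key]))
    if len(xs) < 3:
        raise ValueError(f"need >= 3 matched differential pairs, got {len(xs)}")
    rho, p = stats.spearmanr(xs, ys)
    return {"rho": float(rho), "p_value": float(p), "n": len(xs)}


def agreement_with_experiments(rdr_dominants: Mapping[tuple[str, str], str],
                               external_dominants: Mapping[tuple[str, str], str],
                               ) -> dict:
    """Agreement between RDR dominance calls and external per-pair calls.

    Both mappings must cover the same pair keys.  Each call is reduced to
    a binary label — is the dominant the first-listed taxon of the pair —
    and Cohen's kappa is computed on those labels alongside the raw
    agreement proportion.
    """
    keys_r, keys_e = set(rdr_dominants), set(external_dominants)
    if keys_r != keys_e:
        missing = sorted(keys_r ^ keys_e)
        raise KeyError(f"pair keys differ between mappings: {missing}")
    keys = sorted(keys_r)
    lab_r = np.array([rdr_dominants[k] == k[0] for k in keys], dtype=int)
    lab_e = np.array([external_dominants[k] == k[0] for k in keys], dtype=int)
    n = len(keys)
    n_agree = int((lab_r == lab_e).sum())
    po = n_agree / n
    pe = float(np.mean(lab_r) * np.mean(lab_e)
               + (1 - np.mean(lab_r)) * (1 - np.mean(lab_e)))
    kappa = 0.0 if pe == 1.0 else (po - pe) / (1 - pe)
    return {"n": n, "n_agree": n_agree, "proportion": po, "kappa": float(kappa)}
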