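"""The Relative Dispersion Ratio (RDR) and its per-pair random-effects test.

For two taxa a and b that both colonize a recipient during one FMT
experiment, the RDR is

    RDR(a, b) = log10( (R_a / R_b) / (D_a / D_b) )

with R the post-FMT recipient relative abundances and D the donor
relative abundances.  Because it is a log-ratio of ratios within single
samples, the statistic is invariant to the compositional closure of
either sample: rescaling a sample or re-closing it after adding or
removing unrelated taxa leaves every RDR unchanged.

Across the experiments in which a pair co-colonizes, the per-pair mean
RDR is estimated as the intercept of a random-effects model

    RDR ~ 1 + (1 | subject_id) + (1 | donor_id)

fitted by REML; pairs whose intercept differs from zero at FDR < 0.1
(Benjamini-Hochberg) are called *differentially dispersing*, and the
sign of the intercept names the dominant (better-dispersing) partner.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests

from .triads_io import AbundanceTable, ColonizationProfile, Triad

logger = logging.getLogger(__name__)

OBSERVATION_COLUMNS = ["taxon_a", "taxon_b", "experiment_id", "study_id",
                       "subject_id", "donor_id", "rdr"]


@dataclass(frozen=True)
class RdrObservation:
    """One pair of co-colonizing taxa in one FMT experiment."""

    taxon_a: str
    taxon_b: str
    experiment_id: str
    study_id: str
    subject_id: str
    donor_id: str
    rdr: float

    def __post_init__(self) -> None:
        if not self.taxon_a < self.taxon_b:
            raise ValueError("pair must be canonically ordered: taxon_a < taxon_b")
        if not np.isfinite(self.rdr):
            raise ValueError("RDR must be finite")


@dataclass
class PairSummary:
    """Fit summary for one taxon pair across its experiments."""

    taxon_a: str
    taxon_b: str
    mean_rdr: float
    p_value: float
    n_experiments: int
    n_studies: int
    q_value: float = np.nan
    is_differential: bool = False
    model: str = "mixed"  # mixed | mixed_subject | mixed_donor | ttest

    @property
    def dominant(self) -> str | None:
        if self.mean_rdr > 0:
            return self.taxon_a
        if self.mean_rdr < 0:
            return self.taxon_b
        return None


def compute_rdr(d_a: float, d_b: float, r_a: float, r_b: float) -> float:
    """log10 of the post-FMT to donor fold change of the a:b abundance ratio.

    Defined only for co-colonizers: all four abundances must be strictly
    positive.
    """
    if min(d_a, d_b, r_a, r_b) <= 0:
        raise ValueError(
            "RDR requires strictly positive abundances for both taxa in "
            f"both samples; got D=({d_a}, {d_b}), R=({r_a}, {r_b})")
    return float(np.log10((r_a / r_b) / (d_a / d_b)))


def enumerate_pair_observations(
    triads: Iterable[Triad],
    profiles: Mapping[str, ColonizationProfile],
    table: AbundanceTable,
) -> pd.DataFrame:
    """One RDR observation per unordered colonizer pair per experiment.

    Pairs are canonicalized lexicographically (taxon_a < taxon_b); grouping
    metadata (study, subject, donor) is copied from the triad.
    """
    rows: list[tuple] = []
    for triad in triads:
        colonizers = sorted(profiles[triad.experiment_id].colonizers)
        if len(colonizers) < 2:
            continue
        donor = table.values.loc[triad.donor_sample, colonizers].to_numpy()
        post = table.values.loc[triad.post_sample, colonizers].to_numpy()
        logfc = np.log10(post) - np.log10(donor)
        for i, j in itertools.combinations(range(len(colonizers)), 2):
            rows.append((colonizers[i], colonizers[j], triad.experiment_id,
                         triad.study_id, triad.subject_id, triad.donor_id,
                         float(logfc[i] - logfc[j])))
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def filter_prevalent_pairs(observations: pd.DataFrame, min_studies: int = 2,
                           min_experiments: int = 10) -> set[tuple[str, str]]:
    """Pairs co-colonizing in >= ``min_studies`` distinct studies AND
    >= ``min_experiments`` experiments (both bounds inclusive)."""
    if observations.empty:
        return set()
    grouped = observations.groupby(["taxon_a", "taxon_b"], sort=True)
    counts = grouped.agg(n_studies=("study_id", "nunique"),
                         n_experiments=("experiment_id", "nunique"))
    mask = ((counts["n_studies"] >= min_studies)
            & (counts["n_experiments"] >= min_experiments))
    return set(counts.index[mask])


def _has_repeats(labels: pd.Series) -> bool:
    return labels.nunique() < len(labels)


def _dummies(labels: pd.Series) -> np.ndarray:
    codes, _ = pd.factorize(labels, sort=True)
    out = np.zeros((len(codes), codes.max() + 1))
    out[np.arange(len(codes)), codes] = 1.0
    return out


def _fit_mixed(values: np.ndarray, groups: dict[str, pd.Series]) -> tuple[float, float, float, str]:
    """REML fit of an intercept-only model with random intercepts.

    Returns (intercept, se, df, model_tag).  With two grouping factors the
    random intercepts are crossed, implemented as variance components over
    a single trivial group.  The Wald test uses containment-style degrees
    of freedom: one less than the number of levels of the sparsest factor.
    """
    from statsmodels.regression.mixed_linear_model import VCSpec

    n = len(values)
    exog = np.ones((n, 1))
    n_levels = [labels.nunique() for labels in groups.values()]
    if len(groups) == 2:
        # crossed random intercepts as variance components in one group
        names = list(groups)
        mats = [[_dummies(groups[name])] for name in names]
        vcs = VCSpec(names, [[[f"{nm}[{i}]" for i in range(m[0].shape[1])]]
                             for nm, m in zip(names, mats)], mats)
        # with exog_vc given and exog_re omitted, no per-group random
        # intercept is added; only the two variance components remain
        model = MixedLM(values, exog, groups=np.zeros(n), exog_vc=vcs)
        tag = "mixed"
    else:
        (name, labels), = groups.items()
        codes, _ = pd.factorize(labels, sort=True)
        model = MixedLM(values, exog, groups=codes)
        tag = f"mixed_{name}"
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
        intercept = float(fit.fe_params[0])
        se = float(fit.bse_fe[0])
    if not np.isfinite(se) or se <= 0:
        raise np.linalg.LinAlgError("non-finite standard error")
    df = min(n_levels) - 1
    return intercept, se, max(df, 1), tag


def fit_pair_model(observations: pd.DataFrame, min_observations: int = 2,
                   ) -> PairSummary:
    """Estimate a pair's mean RDR and test it against zero.

    The full model has crossed random intercepts for subject and donor.
    A grouping factor whose levels are all singletons carries no
    information and is dropped; with both factors singular the model
    degrades to a one-sample t-test.  Fit failures walk the same fallback
    chain (drop donor -> drop subject -> t-test), each step logged.

    Inference on the intercept uses a t reference with containment
    degrees of freedom (levels of the sparsest retained factor minus one);
    the t-test branch uses n - 1.
    """
    obs = observations
    n = len(obs)
    if n < min_observations:
        raise ValueError(f"need >= {min_observations} observations, got {n}")
    taxon_a = str(obs["taxon_a"].iloc[0])
    taxon_b = str(obs["taxon_b"].iloc[0])
    values = obs["rdr"].to_numpy(dtype=float)
    n_studies = int(obs["study_id"].nunique())

    candidates: list[dict[str, pd.Series]] = []
    subject_rep = _has_repeats(obs["subject_id"])
    donor_rep = _has_repeats(obs["donor_id"])
    if subject_rep and donor_rep:
        candidates.append({"subject_id": obs["subject_id"],
                           "donor_id": obs["donor_id"]})
    if subject_rep:
        candidates.append({"subject_id": obs["subject_id"]})
    if donor_rep:
        candidates.append({"donor_id": obs["donor_id"]})

    intercept = se = df = None
    tag = "ttest"
    if np.ptp(values) == 0.0:
        # degenerate: no variance at all
        intercept = float(values[0])
        p = 1.0 if intercept == 0 else 0.0
        return PairSummary(taxon_a, taxon_b, intercept, p, n, n_studies,
                           model="constant")
    for groups in candidates:
        try:
            intercept, se, df, tag = _fit_mixed(values, groups)
            break
        except (np.linalg.LinAlgError, ValueError) as exc:
            logger.debug("fit_pair_model(%s, %s): %s fit failed (%s); "
                         "falling back", taxon_a, taxon_b,
                         "+".join(groups), exc)
            intercept = None
    if intercept is None:
        if not candidates:
            logger.debug("fit_pair_model(%s, %s): no grouping repeats; "
                         "one-sample t-test", taxon_a, taxon_b)
        intercept = float(values.mean())
        se = float(values.std(ddof=1) / np.sqrt(n))
        df = n - 1
        tag = "ttest"
    if se == 0:
        p = 1.0 if intercept == 0 else 0.0
    else:
        t = intercept / se
        p = float(2.0 * stats.t.sf(abs(t), df))
    return PairSummary(taxon_a, taxon_b, float(intercept), p, n, n_studies,
                       model=tag)


def fit_all_pairs(observations: pd.DataFrame,
                  pairs: Iterable[tuple[str, str]] | None = None,
                  ) -> list[PairSummary]:
    """Fit the per-pair model for every (or the given set of) pairs."""
    if pairs is not None:
        pairs = set(pairs)
    summaries = []
    for key, group in observations.groupby(["taxon_a", "taxon_b"], sort=True):
        if pairs is not None and key not in pairs:
            continue
        if len(group) < 2:
            continue
        summaries.append(fit_pair_model(group))
    return summaries


def fdr_adjust(p_values: Sequence[float], method: str = "bh") -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    if method != "bh":
        raise ValueError(f"unsupported FDR method {method!r}")
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if (p < 0).any() or (p > 1).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential_pairs(summaries: Sequence[PairSummary],
                            q_threshold: float = 0.1) -> list[PairSummary]:
    """Populate q-values across the family of pairs and flag pairs with
    q strictly below ``q_threshold`` as differentially dispersing."""
    if not summaries:
        return []
    q = fdr_adjust([s.p_value for s in summaries])
    for s, qv in zip(summaries, q):
        s.q_value = float(qv)
        s.is_differential = bool(qv < q_threshold)
    return [s for s in summaries if s.is_differential]


def leave_one_study_out(observations: pd.DataFrame,
                        pairs: Iterable[tuple[str, str]],
                        ) -> tuple[pd.DataFrame, float]:
    """Sign-consistency of the mean RDR under leave-one-study-out.

    For each pair and each study the pair appears in, the sign of the
    pair's mean RDR within that study is compared against the sign of the
    model intercept refitted on all remaining studies.  Returns the
    per-comparison table and the overall agreement fraction.
    """
    rows = []
    grouped = dict(tuple(observations.groupby(["taxon_a", "taxon_b"])))
    for pair in sorted(set(pairs)):
        obs = grouped.get(pair)
        if obs is None:
            continue
        studies = obs["study_id"].unique()
        if len(studies) < 2:
            logger.warning("leave_one_study_out: pair %s in <2 studies; skipped",
                           pair)
            continue
        for study in sorted(studies):
            held = obs[obs["study_id"] == study]
            rest = obs[obs["study_id"] != study]
            if len(rest) < 2:
                continue
            sign_in = np.sign(held["rdr"].mean())
            sign_out = np.sign(fit_pair_model(rest).mean_rdr)
            rows.append((pair[0], pair[1], study,
                         float(sign_in), float(sign_out),
                         bool(sign_in == sign_out)))
    frame = pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "held_out_study",
                                        "sign_in_study", "sign_elsewhere",
                                        "agree"])
    fraction = float(frame["agree"].mean()) if len(frame) else float("nan")
    return frame, fraction


def phylum_dominance_rates(summaries: Sequence[PairSummary],
                           taxon_meta: pd.DataFrame,
                           ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-genus dominance rates and pairwise phylum-level rank-sum tests.

    A genus's dominance rate is the fraction of differential pairs
    containing it in which it is the dominant partner; genera appearing in
    no differential pair are excluded.  Phyla are compared by two-sided
    Mann-Whitney tests on their genus rate vectors.
    """
    diff = [s for s in summaries if s.is_differential]
    n_pairs: dict[str, int] = {}
    n_dom: dict[str, int] = {}
    for s in diff:
        for taxon in (s.taxon_a, s.taxon_b):
            n_pairs[taxon] = n_pairs.get(taxon, 0) + 1
            if s.dominant == taxon:
                n_dom[taxon] = n_dom.get(taxon, 0) + 1
    rate_rows = []
    for taxon in sorted(n_pairs):
        phylum = None
        if taxon in taxon_meta.index and "phylum" in taxon_meta.columns:
            phylum = taxon_meta.loc[taxon, "phylum"]
        rate_rows.append((taxon, phylum, n_pairs[taxon],
                          n_dom.get(taxon, 0) / n_pairs[taxon]))
    rates = pd.DataFrame(rate_rows, columns=["taxon", "phylum", "n_pairs",
                                             "dominance_rate"])
    tests = []
    phyla = sorted(p for p in rates["phylum"].dropna().unique())
    for pa, pb in itertools.combinations(phyla, 2):
        xa = rates.loc[rates["phylum"] == pa, "dominance_rate"]
        xb = rates.loc[rates["phylum"] == pb, "dominance_rate"]
        if len(xa) == 0 or len(xb) == 0:
            continue
        if np.ptp(np.concatenate([xa, xb])) == 0:
            stat, p = np.nan, 1.0
        else:
            stat, p = stats.mannwhitneyu(xa, xb, alternative="two-sided")
        tests.append((pa, pb, float(xa.median()), float(xb.median()),
                      float(stat) if np.isfinite(stat) else np.nan, float(p)))
    tests = pd.DataFrame(tests, columns=["phylum_a", "phylum_b", "median_a",
                                         "median_b", "statistic", "p_value"])
    return rates, tests


def summaries_to_frame(summaries: Sequence[PairSummary]) -> pd.DataFrame:
    """Flat table of pair summaries for serialization."""
    rows = [(s.taxon_a, s.taxon_b, s.mean_rdr, s.p_value, s.q_value,
             s.n_experiments, s.n_studies, s.dominant or "",
             s.is_differential, s.model) for s in summaries]
    return pd.DataFrame(rows, columns=["taxon_a", "taxon_b", "mean_rdr",
                                       "p_value", "q_value", "n_experiments",
                                       "n_studies", "dominant",
                                       "is_differential", "model"])
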