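"""Post-FMT abundance prediction and per-feature attribution.

One random-forest regressor is trained per taxon to predict its
post-FMT relative abundance from the full pre-FMT profiles of donor and
recipient (2 x n_taxa features).  Models are scored by the Spearman
correlation between observed abundances and pooled out-of-fold
predictions under grouped k-fold cross-validation (folds grouped by
recipient so a subject's experiments never straddle train and test);
taxa with rho > 0.3 and BH-corrected p < 0.05 are *well-predicted*.

Feature contributions use an exactly additive tree-path decomposition:
walking each tree from root to leaf, the change in node mean at every
split is credited to the feature split on, so for every prediction
baseline + sum of contributions reconstructs the forest output to
floating-point accuracy.  Contributions are aggregated per feature as
mean absolute values and compared across three feature categories —
Self (the predicted taxon itself), Partner (taxa forming a
differentially dispersing pair with it), Non-partner (all others).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import GroupKFold, KFold

from .rdr_stats import PairSummary, fdr_adjust
from .triads_io import AbundanceTable, Triad

logger = logging.getLogger(__name__)

CATEGORY_SELF = "self"
CATEGORY_PARTNER = "partner"
CATEGORY_NON_PARTNER = "non_partner"


@dataclass
class PredictionEvaluation:
    """Cross-validated performance of one taxon's model."""

    taxon: str
    spearman_rho: float
    p_value: float
    r_squared: float
    q_value: float = np.nan
    well_predicted: bool = False
    constant_target: bool = False


def build_feature_table(triads: Sequence[Triad], table: AbundanceTable,
                        ) -> tuple[pd.DataFrame, pd.DataFrame, pd.Series]:
    """Per-experiment features and targets.

    Features concatenate the donor profile and the recipient pre-FMT
    profile (columns labelled ``donor:<taxon>`` / ``recipient:<taxon>``);
    targets are the post-FMT abundances, one column per taxon.  Also
    returns the subject id per experiment for grouped cross-validation.
    """
    exp_ids = [t.experiment_id for t in triads]
    donor = table.values.loc[[t.donor_sample for t in triads]].to_numpy()
    pre = table.values.loc[[t.pre_sample for t in triads]].to_numpy()
    post = table.values.loc[[t.post_sample for t in triads]].to_numpy()
    taxa = list(table.taxon_ids)
    feat_cols = [f"donor:{t}" for t in taxa] + [f"recipient:{t}" for t in taxa]
    features = pd.DataFrame(np.hstack([donor, pre]), index=exp_ids,
                            columns=feat_cols)
    targets = pd.DataFrame(post, index=exp_ids, columns=taxa)
    subjects = pd.Series([t.subject_id for t in triads], index=exp_ids,
                         name="subject_id")
    return features, targets, subjects


def parse_feature_label(label: str) -> tuple[str, str]:
    """Split ``source:taxon`` feature labels."""
    source, taxon = label.split(":", 1)
    return source, taxon


def _cross_val_predict(x: np.ndarray, y: np.ndarray, groups: np.ndarray | None,
                       n_folds: int, seed: int, n_estimators: int) -> np.ndarray:
    n = len(y)
    preds = np.full(n, np.nan)
    if groups is not None and len(np.unique(groups)) >= n_folds:
        splitter = GroupKFold(n_splits=n_folds)
        splits = splitter.split(x, y, groups)
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = splitter.split(x, y)
    for train, test in splits:
        model = RandomForestRegressor(n_estimators=n_estimators,
                                      random_state=seed, n_jobs=1)
        model.fit(x[train], y[train])
        preds[test] = model.predict(x[test])
    return preds


def _clustered_spearman_p(rho: float, n: int,
                          groups: np.ndarray | None) -> float:
    """Two-sided p-value for a Spearman rho with cluster-aware df.

    Experiments from the same recipient share their donor and pre-FMT
    feature rows, so their out-of-fold predictions coincide and the
    correlation's effective sample size is the number of recipients, not
    of experiments.  The usual t approximation with n-based df is
    anticonservative in that situation; using the cluster count restores
    (slightly conservative) null calibration.
    """
    m = int(len(np.unique(groups))) if groups is not None else n
    df = max(m - 2, 1)
    if abs(rho) >= 1.0:
        return 0.0
    t = rho * np.sqrt(df / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df))


def fit_predictors(features: pd.DataFrame, targets: pd.DataFrame,
                   n_folds: int = 10, seed: int = 17,
                   subjects: pd.Series | None = None,
                   n_estimators: int = 500,
                   ) -> list[PredictionEvaluation]:
    """Cross-validated per-taxon evaluation with BH correction across taxa.

    Spearman rho and R^2 (1 - SS_res/SS_tot) are computed on pooled
    out-of-fold predictions.  Constant targets cannot be rank-scored and
    are flagged and excluded from the FDR family.
    """
    n = len(features)
    if n < n_folds:
        raise ValueError(f"need >= {n_folds} experiments for {n_folds}-fold "
                         f"cross-validation, got {n}")
    x = features.to_numpy()
    groups = subjects.loc[features.index].to_numpy() if subjects is not None else None
    evaluations: list[PredictionEvaluation] = []
    for taxon in targets.columns:
        y = targets[taxon].to_numpy(dtype=float)
        if np.ptp(y) == 0:
            logger.warning("fit_predictors: target %r is constant; skipped", taxon)
            evaluations.append(PredictionEvaluation(
                taxon=taxon, spearman_rho=np.nan, p_value=np.nan,
                r_squared=np.nan, constant_target=True))
            continue
        preds = _cross_val_predict(x, y, groups, n_folds, seed, n_estimators)
        if np.ptp(preds) == 0:
            rho, p = 0.0, 1.0
        else:
            rho, _ = stats.spearmanr(y, preds)
            p = _clustered_spearman_p(rho, n, groups)
        ss_res = float(np.sum((y - preds) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        evaluations.append(PredictionEvaluation(
            taxon=taxon, spearman_rho=float(rho), p_value=float(p),
            r_squared=1.0 - ss_res / ss_tot))
    scored = [e for e in evaluations if not e.constant_target]
    if scored:
        q = fdr_adjust([e.p_value for e in scored])
        for e, qv in zip(scored, q):
            e.q_value = float(qv)
            e.well_predicted = bool(e.spearman_rho > 0.3 and qv < 0.05)
    return evaluations


def tree_path_attributions(model: RandomForestRegressor,
                           x: np.ndarray) -> tuple[np.ndarray, float]:
    """Additive decomposition of forest predictions along decision paths.

    Returns (attributions, baseline) with attributions of shape
    (n_samples, n_features); for every sample,
    ``baseline + attributions.sum()`` equals the forest prediction.
    """
    n_samples, n_features = x.shape
    total = np.zeros((n_samples, n_features))
    baseline = 0.0
    for est in model.estimators_:
        tree = est.tree_
        node_values = tree.value[:, 0, 0]
        left, right = tree.children_left, tree.children_right
        feature = tree.feature
        n_nodes = tree.node_count
        # credit the value change at each child to its parent's split feature
        parent_feature = np.full(n_nodes, -1)
        delta = np.zeros(n_nodes)
        for node in range(n_nodes):
            for child in (left[node], right[node]):
                if child != -1:
                    parent_feature[child] = feature[node]
                    delta[child] = node_values[child] - node_values[node]
        indicator = est.decision_path(x)  # sparse n_samples x n_nodes
        credit = np.zeros((n_nodes, n_features))
        nonroot = np.flatnonzero(parent_feature >= 0)
        credit[nonroot, parent_feature[nonroot]] = delta[nonroot]
        total += indicator @ credit
        baseline += node_values[0]
    n_trees = len(model.estimators_)
    return total / n_trees, baseline / n_trees


def categorize_features(model_taxon: str, feature_labels: Sequence[str],
                        partner_map: Mapping[str, set[str]]) -> pd.DataFrame:
    """Label each feature self / partner / non_partner for one model."""
    partners = partner_map.get(model_taxon, set())
    rows = []
    for label in feature_labels:
        source, taxon = parse_feature_label(label)
        if taxon == model_taxon:
            cat = CATEGORY_SELF
        elif taxon in partners:
            cat = CATEGORY_PARTNER
        else:
            cat = CATEGORY_NON_PARTNER
        rows.append((label, source, taxon, cat))
    return pd.DataFrame(rows, columns=["feature", "source", "taxon", "category"])


def partner_map_from_pairs(pairs: Iterable[PairSummary]) -> dict[str, set[str]]:
    """taxon -> set of partners in differentially dispersing pairs."""
    mapping: dict[str, set[str]] = {}
    for s in pairs:
        if not s.is_differential:
            continue
        mapping.setdefault(s.taxon_a, set()).add(s.taxon_b)
        mapping.setdefault(s.taxon_b, set()).add(s.taxon_a)
    return mapping


def attribution_by_category(features: pd.DataFrame, targets: pd.DataFrame,
                            evaluations: Sequence[PredictionEvaluation],
                            pairs: Sequence[PairSummary],
                            seed: int = 17, n_estimators: int = 500,
                            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-feature attributions for well-predicted taxa with partners,
    aggregated by category, plus rank-based category comparisons.

    For each analyzed model the forest is refitted on all experiments and
    each feature's mean absolute attribution is recorded together with
    its source (donor/recipient) and category.  Categories are compared
    across models with two-sided rank-sum tests, BH-corrected, both
    pooled and split by source.
    """
    partner_map = partner_map_from_pairs(pairs)
    analyzed = [e for e in evaluations
                if e.well_predicted and partner_map.get(e.taxon)]
    skipped = [e.taxon for e in evaluations
               if e.well_predicted and not partner_map.get(e.taxon)]
    if skipped:
        logger.info("attribution_by_category: %d well-predicted taxa have no "
                    "partner and are excluded: %s", len(skipped), skipped[:5])
    x = features.to_numpy()
    records = []
    for ev in analyzed:
        y = targets[ev.taxon].to_numpy(dtype=float)
        model = RandomForestRegressor(n_estimators=n_estimators,
                                      random_state=seed, n_jobs=1)
        model.fit(x, y)
        attrib, _ = tree_path_attributions(model, x)
        mean_abs = np.abs(attrib).mean(axis=0)
        cats = categorize_features(ev.taxon, features.columns, partner_map)
        for (_, row), value in zip(cats.iterrows(), mean_abs):
            records.append((ev.taxon, row["feature"], row["source"],
                            row["taxon"], row["category"], float(value)))
    table = pd.DataFrame(records, columns=["model_taxon", "feature", "source",
                                           "feature_taxon", "category",
                                           "mean_abs_attribution"])
    tests = _category_tests(table)
    return table, tests


def _category_tests(table: pd.DataFrame) -> pd.DataFrame:
    """Pairwise category comparisons of per-model mean attributions."""
    rows = []
    scopes = [("all", table)]
    for source in sorted(table["source"].unique()) if len(table) else []:
        scopes.append((source, table[table["source"] == source]))
    for scope, sub in scopes:
        per_model = (sub.groupby(["model_taxon", "category"])
                     ["mean_abs_attribution"].mean().unstack())
        for cat_a, cat_b in itertools.combinations(
                [CATEGORY_SELF, CATEGORY_PARTNER, CATEGORY_NON_PARTNER], 2):
            if cat_a not in per_model.columns or cat_b not in per_model.columns:
                continue
            a = per_model[cat_a].dropna()
            b = per_model[cat_b].dropna()
            if len(a) == 0 or len(b) == 0:
                continue
            if np.ptp(np.concatenate([a, b])) == 0:
                stat, p = np.nan, 1.0
            else:
                stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
            rows.append((scope, cat_a, cat_b, len(a), float(np.median(a)),
                         float(np.median(b)),
                         float(stat) if np.isfinite(stat) else np.nan,
                         float(p)))
    tests = pd.DataFrame(rows, columns=["scope", "category_a", "category_b",
                                        "n_models", "median_a", "median_b",
                                        "statistic", "p_value"])
    if len(tests):
        tests["q_value"] = fdr_adjust(tests["p_value"].tolist())
    else:
        tests["q_value"] = pd.Series(dtype=float)
    return tests


def evaluations_to_frame(evaluations: Sequence[PredictionEvaluation],
                         ) -> pd.DataFrame:
    rows = [(e.taxon, e.spearman_rho, e.p_value, e.q_value, e.r_squared,
             e.well_predicted, e.constant_target) for e in evaluations]
    return pd.DataFrame(rows, columns=["taxon", "spearman_rho", "p_value",
                                       "q_value", "r_squared",
                                       "well_predicted", "constant_target"])
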