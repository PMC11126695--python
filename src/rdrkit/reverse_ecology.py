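"""Reverse-ecology metabolic scoring of taxa from KO gene content.

Each genus's KO repertoire is expanded into a directed compound graph
(substrate -> product per reaction).  The *seed set* — compounds the
organism cannot synthesize and must acquire from its environment — is
read off the condensation of that graph: every compound in a source
strongly connected component (condensation in-degree zero) is a seed,
with confidence 1/|component|.  From seed sets we derive:

* nutritional flexibility — the fraction of network compounds that are
  seeds, a proxy for the breadth of usable nutritional inputs;
* the metabolic competition index — the confidence-weighted fraction of
  the focal taxon's seeds shared with another taxon's seed set, an
  asymmetric proxy for the competition the focal taxon experiences in
  the other's presence.

Pathway scores count KOs per pathway, with multi-pathway KOs split
fractionally so total mass is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .rdr_stats import PairSummary, fdr_adjust

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Reaction:
    """One reaction: substrates are consumed, products produced."""

    reaction_id: str
    substrates: tuple[str, ...]
    products: tuple[str, ...]
    reversible: bool = False

    def __post_init__(self) -> None:
        if not self.substrates or not self.products:
            raise ValueError(
                f"reaction {self.reaction_id!r} needs >=1 substrate and product")


@dataclass
class MetabolicNetwork:
    """Directed compound graph for one genus."""

    graph: nx.DiGraph
    genus_id: str = ""
    uncovered_kos: tuple[str, ...] = ()

    @property
    def compounds(self) -> set[str]:
        return set(self.graph.nodes)


@dataclass
class SeedSet:
    """Seed compounds with confidences (1/|source SCC| per member)."""

    confidence: dict[str, float] = field(default_factory=dict)
    scc_sizes: dict[str, int] = field(default_factory=dict)

    @property
    def compounds(self) -> set[str]:
        return set(self.confidence)

    def total_confidence(self) -> float:
        return float(sum(self.confidence.values()))


def build_network(ko_set: Iterable[str],
                  reaction_db: Mapping[str, Sequence[Reaction]],
                  genus_id: str = "",
                  exclude_compounds: Iterable[str] = ()) -> MetabolicNetwork:
    """Union the substrate->product edges of every reaction of every KO.

    KOs missing from ``reaction_db`` are skipped and reported in
    ``uncovered_kos``.  ``exclude_compounds`` removes currency metabolites
    (ATP, water, ...) before graph construction if a list is supplied.
    """
    excluded = set(exclude_compounds)
    graph = nx.DiGraph()
    uncovered = []
    for ko in sorted(set(ko_set)):
        reactions = reaction_db.get(ko)
        if reactions is None:
            uncovered.append(ko)
            continue
        for rxn in reactions:
            subs = [c for c in rxn.substrates if c not in excluded]
            prods = [c for c in rxn.products if c not in excluded]
            for s in subs:
                for p in prods:
                    graph.add_edge(s, p)
                    if rxn.reversible:
                        graph.add_edge(p, s)
    if uncovered:
        logger.info("build_network(%s): %d/%d KOs not in reaction_db",
                    genus_id, len(uncovered),
                    len(uncovered) + len(set(ko_set)) - len(uncovered))
    return MetabolicNetwork(graph=graph, genus_id=genus_id,
                            uncovered_kos=tuple(uncovered))


def seed_set(network: MetabolicNetwork) -> SeedSet:
    """Seeds = compounds in source SCCs of the compound graph.

    The graph is condensed to its DAG of strongly connected components;
    every compound in a component with condensation in-degree zero is a
    seed with confidence 1/|component|.
    """
    graph = network.graph
    if graph.number_of_nodes() == 0:
        raise ValueError("cannot compute seed set of an empty network")
    condensation = nx.condensation(graph)
    confidence: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for comp_id in condensation.nodes:
        if condensation.in_degree(comp_id) == 0:
            members = condensation.nodes[comp_id]["members"]
            conf = 1.0 / len(members)
            for compound in members:
                confidence[compound] = conf
                sizes[compound] = len(members)
    return SeedSet(confidence=confidence, scc_sizes=sizes)


def nutritional_flexibility(network: MetabolicNetwork, seeds: SeedSet) -> float:
    """Fraction of the network's compounds that are seed metabolites."""
    n = network.graph.number_of_nodes()
    if n == 0:
        raise ValueError("nutritional flexibility undefined for empty network")
    return len(seeds.compounds) / n


def competition_index(seeds_focal: SeedSet, seeds_other: SeedSet) -> float:
    """Confidence-weighted overlap of the focal taxon's seeds with the
    other taxon's seed set, normalized by the focal total confidence.

    Asymmetric: quantifies the competition the focal taxon may experience
    in the presence of the other.  Lies in [0, 1]; 1 for identical sets.
    """
    total = seeds_focal.total_confidence()
    if total <= 0:
        raise ValueError("focal seed set is empty")
    shared = seeds_focal.compounds & seeds_other.compounds
    overlap = sum(seeds_focal.confidence[c] for c in shared)
    return float(overlap / total)


def pathway_scores(ko_set: Iterable[str],
                   pathway_map: Mapping[str, Sequence[str]]) -> pd.Series:
    """Fractional KO counts per pathway.

    A KO mapped to m pathways contributes 1/m to each, so the scores sum
    to the number of KOs with at least one pathway assignment.
    """
    kos = sorted(set(ko_set))
    scores: dict[str, float] = {}
    uncovered = 0
    for ko in kos:
        pathways = pathway_map.get(ko) or ()
        if not pathways:
            uncovered += 1
            continue
        w = 1.0 / len(set(pathways))
        for pw in set(pathways):
            scores[pw] = scores.get(pw, 0.0) + w
    if uncovered:
        logger.info("pathway_scores: %d/%d KOs without pathway assignment",
                    uncovered, len(kos))
    return pd.Series(scores, dtype=float).sort_index()


def _paired_partner_values(pairs: Sequence[PairSummary],
                           metric: Mapping[str, float]) -> tuple[np.ndarray, np.ndarray]:
    dom_vals, min_vals = [], []
    for s in pairs:
        dom = s.dominant
        if dom is None:
            continue
        minor = s.taxon_b if dom == s.taxon_a else s.taxon_a
        if dom not in metric or minor not in metric:
            logger.warning("compare_dominant_minor: pair (%s, %s) missing a "
                           "metric value; excluded", s.taxon_a, s.taxon_b)
            continue
        dom_vals.append(metric[dom])
        min_vals.append(metric[minor])
    return np.asarray(dom_vals, dtype=float), np.asarray(min_vals, dtype=float)


def _signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    if np.all(x == y):
        return np.nan, 1.0
    stat, p = stats.wilcoxon(x, y, alternative="two-sided")
    return float(stat), float(p)


def compare_dominant_minor(pairs: Sequence[PairSummary], mode: str,
                           flexibility: Mapping[str, float] | None = None,
                           competition: Mapping[tuple[str, str], float] | None = None,
                           pathway_table: pd.DataFrame | None = None,
                           fold_threshold: float = 2.0,
                           q_threshold: float = 0.1) -> dict | pd.DataFrame:
    """Dominant-vs-minor partner comparison across differential pairs.

    ``mode='flexibility'``: paired two-sided signed-rank test on per-genus
    nutritional flexibility of dominant vs minor partners.

    ``mode='competition'``: paired signed-rank on the competition the
    dominant experiences from the minor vs the reverse; ``competition``
    maps ordered (focal, other) genus pairs to the index.

    ``mode='pathway'``: with ``pathway_table`` (genus x pathway scores),
    restrict to pathways whose dominant/minor mean score ratio is at least
    ``fold_threshold`` (or its reciprocal), test each with a two-sided
    rank-sum test, BH-correct, and report the enrichment sign.
    """
    diff = [s for s in pairs if s.is_differential]
    if mode == "flexibility":
        if flexibility is None:
            raise ValueError("flexibility mode requires a metric mapping")
        x, y = _paired_partner_values(diff, flexibility)
        if len(x) == 0:
            raise ValueError("no pairs with flexibility values")
        stat, p = _signed_rank(x, y)
        return {"mode": mode, "n_pairs": len(x), "statistic": stat,
                "p_value": p, "median_dominant": float(np.median(x)),
                "median_minor": float(np.median(y))}
    if mode == "competition":
        if competition is None:
            raise ValueError("competition mode requires pairwise indices")
        x, y = [], []
        for s in diff:
            dom = s.dominant
            if dom is None:
                continue
            minor = s.taxon_b if dom == s.taxon_a else s.taxon_a
            if (dom, minor) not in competition or (minor, dom) not in competition:
                logger.warning("compare_dominant_minor: pair (%s, %s) missing "
                               "competition indices; excluded", s.taxon_a,
                               s.taxon_b)
                continue
            x.append(competition[(dom, minor)])  # felt by dominant
            y.append(competition[(minor, dom)])  # felt by minor
        x, y = np.asarray(x), np.asarray(y)
        if len(x) == 0:
            raise ValueError("no pairs with competition indices")
        stat, p = _signed_rank(x, y)
        return {"mode": mode, "n_pairs": len(x), "statistic": stat,
                "p_value": p, "median_dominant_felt": float(np.median(x)),
                "median_minor_felt": float(np.median(y))}
    if mode == "pathway":
        if pathway_table is None:
            raise ValueError("pathway mode requires a genus x pathway table")
        dom_rows, min_rows = [], []
        for s in diff:
            dom = s.dominant
            if dom is None:
                continue
            minor = s.taxon_b if dom == s.taxon_a else s.taxon_a
            if dom not in pathway_table.index or minor not in pathway_table.index:
                continue
            dom_rows.append(pathway_table.loc[dom])
            min_rows.append(pathway_table.loc[minor])
        if not dom_rows:
            raise ValueError("no pairs with pathway scores")
        dom_tab = pd.DataFrame(dom_rows).reset_index(drop=True)
        min_tab = pd.DataFrame(min_rows).reset_index(drop=True)
        records = []
        for pw in pathway_table.columns:
            mu_d, mu_m = dom_tab[pw].mean(), min_tab[pw].mean()
            if mu_d == 0 and mu_m == 0:
                continue
            ratio = np.inf if mu_m == 0 else mu_d / mu_m
            passes = ratio >= fold_threshold or ratio <= 1.0 / fold_threshold
            if not passes:
                continue
            if np.ptp(np.concatenate([dom_tab[pw], min_tab[pw]])) == 0:
                stat, p = np.nan, 1.0
            else:
                stat, p = stats.mannwhitneyu(dom_tab[pw], min_tab[pw],
                                             alternative="two-sided")
            records.append((pw, float(mu_d), float(mu_m), float(ratio),
                            float(stat) if np.isfinite(stat) else np.nan,
                            float(p), float(np.sign(mu_d - mu_m))))
        result = pd.DataFrame(records, columns=["pathway", "mean_dominant",
                                                "mean_minor", "ratio",
                                                "statistic", "p_value",
                                                "enrichment_sign"])
        if len(result):
            result["q_value"] = fdr_adjust(result["p_value"].tolist())
            result["significant"] = result["q_value"] < q_threshold
        else:
            result["q_value"] = pd.Series(dtype=float)
            result["significant"] = pd.Series(dtype=bool)
        return result
    raise ValueError(f"unknown mode {mode!r}")


def read_reaction_db(path) -> dict[str, list[Reaction]]:
    """Read a KO -> reactions table (TSV: ko, reaction_id, substrates,
    products, reversible; compound lists semicolon-separated)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    db: dict[str, list[Reaction]] = {}
    for _, row in frame.iterrows():
        rxn = Reaction(
            reaction_id=row["reaction_id"],
            substrates=tuple(str(row["substrates"]).split(";")),
            products=tuple(str(row["products"]).split(";")),
            reversible=str(row.get("reversible", "0")).lower() in
            ("1", "true", "yes"),
        )
        db.setdefault(row["ko"], []).append(rxn)
    return db


def read_pathway_map(path) -> dict[str, list[str]]:
    """Read a KO -> pathway table (TSV: ko, pathway_id)."""
    frame = pd.read_csv(path, sep="\t", dtype=str)
    mapping: dict[str, list[str]] = {}
    for _, row in frame.iterrows():
        mapping.setdefault(row["ko"], []).append(row["pathway_id"])
    return mapping


def kos_present(ko_table: pd.DataFrame, genus: str) -> set[str]:
    """KOs with copy number > 0 for one genus in a genus x KO table."""
    row = ko_table.loc[genus]
    return set(row.index[row > 0])
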