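"""Synthetic FMT meta-cohorts with known per-taxon dispersal effects.

The generator emulates the triad structure of an FMT meta-analysis:
studies containing recipients, each recipient linked to a donor (a
configurable fraction of recipients share a donor within a study) and
sampled before FMT and at one or more post-FMT timepoints.

Generative model, per experiment and taxon t:

* donor (unclosed) abundance:  10^(base_t + donor noise), all taxa present;
* recipient pre-FMT: an independent community of the same form, with each
  taxon deleted with probability ``removal_prob`` — deletions create the
  colonization opportunities;
* recipient post-FMT: taxa present pre-FMT carry over unchanged; taxa
  absent pre-FMT colonize at donor_t x 10^(delta_t + u_ts + eps), with
  delta_t the taxon's fixed dispersal propensity, u_ts ~ N(0, sigma_u^2)
  a subject-level effect shared across that subject's timepoints, and
  eps ~ N(0, sigma_e^2) per observation;
* every sample is closed to sum 1.

Because the RDR is a log-ratio of within-sample ratios, closure cancels
and the expected RDR of pair (a, b) is exactly delta_a - delta_b — the
ground truth against which recovery is scored.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cooccurrence import PresenceMatrix
from .reverse_ecology import MetabolicNetwork, Reaction, SeedSet, build_network, seed_set

DEFAULT_SEED = 17


@dataclass
class SyntheticTruth:
    """Planted parameters of a synthetic cohort."""

    delta: dict[str, float]
    sigma_u: float = 0.1
    sigma_e: float = 0.2
    removal_prob: float = 0.5
    donor_sharing: float = 0.2
    seed: int = DEFAULT_SEED
    #: realized per-colonization effects delta + u + eps, for exact checks
    realized_effects: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.removal_prob <= 1.0:
            raise ValueError(f"removal_prob must lie in [0, 1]; got "
                             f"{self.removal_prob}")
        if self.sigma_u < 0 or self.sigma_e < 0:
            raise ValueError("standard deviations must be non-negative")

    def expected_rdr(self, taxon_a: str, taxon_b: str) -> float:
        return self.delta[taxon_a] - self.delta[taxon_b]

    def to_json(self, path) -> None:
        payload = {"delta": self.delta, "sigma_u": self.sigma_u,
                   "sigma_e": self.sigma_e, "removal_prob": self.removal_prob,
                   "donor_sharing": self.donor_sharing, "seed": self.seed}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "SyntheticTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(**payload)


def default_truth(n_taxa: int = 40, delta_spread: float = 0.5,
                  sigma_u: float = 0.1, sigma_e: float = 0.2,
                  removal_prob: float = 0.5, donor_sharing: float = 0.2,
                  seed: int = DEFAULT_SEED) -> SyntheticTruth:
    """Evenly spaced dispersal propensities in [-delta_spread, +delta_spread].

    The assignment of propensities to taxon ids is shuffled (seeded) so
    that dominance direction is unrelated to the lexicographic pair
    orientation, as in real communities.
    """
    taxa = [f"g{i:03d}" for i in range(n_taxa)]
    if n_taxa == 1:
        deltas = np.array([0.0])
    else:
        deltas = np.linspace(-delta_spread, delta_spread, n_taxa)
    deltas = np.random.default_rng(seed).permutation(deltas)
    return SyntheticTruth(delta=dict(zip(taxa, deltas.tolist())),
                          sigma_u=sigma_u, sigma_e=sigma_e,
                          removal_prob=removal_prob,
                          donor_sharing=donor_sharing, seed=seed)


def generate_cohort(n_studies: int = 4, n_subjects_per_study: int = 15,
                    n_timepoints: int = 2, n_taxa: int = 40,
                    truth: SyntheticTruth | None = None,
                    seed: int | None = None,
                    base_log10_range: tuple[float, float] = (-3.0, -1.0),
                    profile_sd: float = 0.4):
    """Generate a triad-structured meta-cohort with known ground truth.

    Returns ``(table, metadata, truth)`` — a closed relative
    :class:`~rdrkit.triads_io.AbundanceTable`, the triad metadata frame,
    and the truth object with realized colonization effects attached.
    Deterministic given the seed.
    """
    from .triads_io import AbundanceTable  # local import to avoid cycle

    if min(n_studies, n_subjects_per_study, n_timepoints, n_taxa) < 1:
        raise ValueError("all cohort dimensions must be positive")
    if truth is None:
        truth = default_truth(n_taxa=n_taxa,
                              seed=DEFAULT_SEED if seed is None else seed)
    if seed is None:
        seed = truth.seed
    taxa = sorted(truth.delta)
    if len(taxa) != n_taxa:
        raise ValueError(f"truth covers {len(taxa)} taxa but n_taxa={n_taxa}")
    deltas = np.array([truth.delta[t] for t in taxa])
    rng = np.random.default_rng(seed)
    base = rng.uniform(*base_log10_range, size=n_taxa)

    samples: dict[str, np.ndarray] = {}
    sample_study: dict[str, str] = {}
    meta_rows = []
    effect_rows = []

    for si in range(n_studies):
        study = f"study{si:02d}"
        shared_donor = f"{study}_donorS"
        shared_profile: np.ndarray | None = None
        for ri in range(n_subjects_per_study):
            subject = f"{study}_subj{ri:02d}"
            shares = rng.random() < truth.donor_sharing
            if shares:
                donor_id = shared_donor
                if shared_profile is None:
                    shared_profile = 10.0 ** (base + rng.normal(0, profile_sd, n_taxa))
                donor_profile = shared_profile
            else:
                donor_id = f"{study}_donor{ri:02d}"
                donor_profile = 10.0 ** (base + rng.normal(0, profile_sd, n_taxa))
            donor_sample = f"{donor_id}_s"
            if donor_sample not in samples:
                samples[donor_sample] = donor_profile
                sample_study[donor_sample] = study
            # recipient pre-FMT: independent community with deletions
            pre_profile = 10.0 ** (base + rng.normal(0, profile_sd, n_taxa))
            absent = rng.random(n_taxa) < truth.removal_prob
            if absent.all():
                # a pre-FMT community is never empty; keep one resident
                absent[rng.integers(n_taxa)] = False
            pre_profile = np.where(absent, 0.0, pre_profile)
            pre_sample = f"{subject}_pre"
            samples[pre_sample] = pre_profile
            sample_study[pre_sample] = study
            u = rng.normal(0, truth.sigma_u, n_taxa)  # shared across timepoints
            for tp in range(1, n_timepoints + 1):
                eps = rng.normal(0, truth.sigma_e, n_taxa)
                effect = deltas + u + eps
                post = np.where(absent, donor_profile * 10.0 ** effect,
                                pre_profile)
                post_sample = f"{subject}_post{tp}"
                samples[post_sample] = post
                sample_study[post_sample] = study
                exp_id = f"{subject}:post{tp}"
                meta_rows.append((exp_id, donor_sample, pre_sample, post_sample,
                                  subject, donor_id, study, tp))
                for ti in np.flatnonzero(absent):
                    effect_rows.append((exp_id, taxa[ti], float(effect[ti])))

    values = pd.DataFrame.from_dict(samples, orient="index", columns=taxa)
    values.index.name = "sample_id"
    values.columns.name = "taxon_id"
    values = values.div(values.sum(axis=1), axis=0)
    sample_meta = pd.DataFrame({
        "read_depth": 10000.0,
        "study_id": pd.Series(sample_study),
    }, index=values.index)
    table = AbundanceTable(values=values, is_relative=True,
                           sample_meta=sample_meta)
    metadata = pd.DataFrame(meta_rows, columns=[
        "experiment_id", "donor_sample", "pre_sample", "post_sample",
        "subject_id", "donor_id", "study_id", "timepoint"])
    truth.realized_effects = pd.DataFrame(
        effect_rows, columns=["experiment_id", "taxon_id", "effect"])
    truth.seed = seed
    return table, metadata, truth


def simulate_pair_observations(delta: float, sigma_u: float, sigma_e: float,
                               n_subjects: int, n_timepoints: int = 2,
                               seed: int = DEFAULT_SEED,
                               taxon_a: str = "a", taxon_b: str = "b",
                               study_ids: Sequence[str] | None = None,
                               rng: np.random.Generator | None = None,
                               ) -> pd.DataFrame:
    """Observations for a single pair drawn directly from the RDR model.

    RDR = delta + u_subject + eps, with u shared across a subject's
    timepoints.  Donors are unique per subject (the donor term is then
    unidentifiable and dropped by the fitter, as in cohorts without donor
    sharing).  Useful for calibration studies at exactly known effect
    sizes.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        u = rng.normal(0, sigma_u)
        study = (study_ids[s % len(study_ids)] if study_ids
                 else f"study{s % 2:02d}")
        for tp in range(1, n_timepoints + 1):
            rdr = delta + u + rng.normal(0, sigma_e)
            rows.append((taxon_a, taxon_b, f"subj{s:03d}:post{tp}", study,
                         f"subj{s:03d}", f"donor{s:03d}", float(rdr)))
    from .rdr_stats import OBSERVATION_COLUMNS
    return pd.DataFrame(rows, columns=OBSERVATION_COLUMNS)


def generate_presence_matrix(n_samples: int, n_taxa: int,
                             segregation: float = 0.0,
                             seed: int = DEFAULT_SEED,
                             n_segregated_pairs: int = 0,
                             occupancy_range: tuple[float, float] = (0.25, 0.75),
                             ) -> tuple[PresenceMatrix, list[tuple[str, str]]]:
    """Random occurrence matrix with optional planted segregation.

    Taxa occur independently at taxon-specific rates; for each of the
    first ``n_segregated_pairs`` disjoint taxon pairs, joint occurrences
    are broken up with probability ``segregation`` (one member removed at
    random), so segregation=1 forces a perfect checkerboard (S_ij = 0).
    """
    if min(n_samples, n_taxa) < 1:
        raise ValueError("dimensions must be positive")
    if not 0.0 <= segregation <= 1.0:
        raise ValueError("segregation must lie in [0, 1]")
    if 2 * n_segregated_pairs > n_taxa:
        raise ValueError("not enough taxa for the requested segregated pairs")
    rng = np.random.default_rng(seed)
    taxa = [f"t{i:03d}" for i in range(n_taxa)]
    rates = rng.uniform(*occupancy_range, size=n_taxa)
    bits = (rng.random((n_samples, n_taxa)) < rates).astype(int)
    pairs = []
    for k in range(n_segregated_pairs):
        i, j = 2 * k, 2 * k + 1
        pairs.append((taxa[i], taxa[j]))
        both = np.flatnonzero((bits[:, i] == 1) & (bits[:, j] == 1))
        for row in both:
            if rng.random() < segregation:
                bits[row, i if rng.random() < 0.5 else j] = 0
    frame = pd.DataFrame(bits, columns=taxa,
                         index=[f"s{i:04d}" for i in range(n_samples)])
    return PresenceMatrix(bits=frame), pairs


#: shipped toy reaction specs with analytically known seed sets
TOY_NETWORK_SPECS: Mapping[str, tuple[list[Reaction], dict[str, float]]] = {
    "chain3": ([Reaction("r1", ("A",), ("B",)), Reaction("r2", ("B",), ("C",))],
               {"A": 1.0}),
    "cycle2": ([Reaction("r1", ("A",), ("B",)), Reaction("r2", ("B",), ("A",))],
               {"A": 0.5, "B": 0.5}),
    "twosource": ([Reaction("r1", ("A",), ("C",)), Reaction("r2", ("B",), ("C",))],
                  {"A": 1.0, "B": 1.0}),
}


def generate_toy_network(spec: str | Sequence[Reaction],
                         ) -> tuple[MetabolicNetwork, SeedSet]:
    """A small metabolic network plus its seed set.

    ``spec`` is a shipped name (chain3, cycle2, twosource) or an explicit
    reaction list; the seed set is always recomputed, and for shipped
    specs it matches the documented analytic expectation.
    """
    if isinstance(spec, str):
        if spec not in TOY_NETWORK_SPECS:
            raise KeyError(f"unknown toy network {spec!r}; "
                           f"available: {sorted(TOY_NETWORK_SPECS)}")
        reactions, _ = TOY_NETWORK_SPECS[spec]
    else:
        reactions = list(spec)
    db = {f"K{i:05d}": [rxn] for i, rxn in enumerate(reactions)}
    network = build_network(db.keys(), db, genus_id=str(spec))
    return network, seed_set(network)


def generate_metabolic_universe(taxa: Sequence[str], seed: int = DEFAULT_SEED,
                                n_compounds: int = 40, n_kos: int = 60,
                                n_pathways: int = 8,
                                ko_presence: float = 0.5,
                                ) -> dict[str, pd.DataFrame]:
    """Random KO content, reaction and pathway tables for a set of genera.

    Purely synthetic plumbing so the reverse-ecology workflow can run
    offline: each KO owns one random reaction (1-2 substrates, 1-2
    products, 20% reversible) and 1-2 pathways; each genus carries each
    KO with probability ``ko_presence``.
    """
    rng = np.random.default_rng(seed)
    compounds = [f"C{i:05d}" for i in range(n_compounds)]
    kos = [f"K{i:05d}" for i in range(n_kos)]
    pathways = [f"map{i:05d}" for i in range(n_pathways)]
    rxn_rows = []
    for i, ko in enumerate(kos):
        k_sub = int(rng.integers(1, 3))
        k_prod = int(rng.integers(1, 3))
        chosen = rng.choice(n_compounds, size=k_sub + k_prod, replace=False)
        subs = [compounds[c] for c in chosen[:k_sub]]
        prods = [compounds[c] for c in chosen[k_sub:]]
        rxn_rows.append((ko, f"R{i:05d}", ";".join(subs), ";".join(prods),
                         int(rng.random() < 0.2)))
    reactions = pd.DataFrame(rxn_rows, columns=["ko", "reaction_id",
                                                "substrates", "products",
                                                "reversible"])
    pw_rows = []
    for ko in kos:
        for pw in rng.choice(n_pathways, size=int(rng.integers(1, 3)),
                             replace=False):
            pw_rows.append((ko, pathways[pw]))
    pathway_map = pd.DataFrame(pw_rows, columns=["ko", "pathway_id"])
    content = (rng.random((len(taxa), n_kos)) < ko_presence).astype(int)
    ko_table = pd.DataFrame(content, index=list(taxa), columns=kos)
    ko_table.index.name = "genus"
    return {"ko_table": ko_table, "reactions": reactions,
            "pathway_map": pathway_map}


def planted_prediction_targets(features: pd.DataFrame,
                               partner_of: Mapping[str, Sequence[str]],
                               coefficient: float = 1.0,
                               noise_sd: float = 0.02,
                               seed: int = DEFAULT_SEED) -> pd.DataFrame:
    """Targets driven by partner features (mode ``prediction``).

    For each model taxon, the target is ``coefficient`` times the sum of
    its partners' donor and recipient features plus Gaussian noise — a
    planted signal for verifying that partner attributions exceed
    non-partner attributions.
    """
    rng = np.random.default_rng(seed)
    targets = {}
    for taxon, partners in partner_of.items():
        signal = np.zeros(len(features))
        for p in partners:
            for col in (f"donor:{p}", f"recipient:{p}"):
                if col in features.columns:
                    signal = signal + coefficient * features[col].to_numpy()
        targets[taxon] = signal + rng.normal(0, noise_sd, len(features))
    return pd.DataFrame(targets, index=features.index)
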