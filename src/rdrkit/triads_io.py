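"""Abundance tables, FMT triads, and colonization-status classification.

An FMT *experiment* is a triad of samples: the donor's stool before
transplant, the recipient before transplant, and the recipient at one
post-transplant timepoint.  A recipient sampled at several post-FMT
timepoints contributes one experiment per timepoint.  Within an
experiment every taxon falls into exactly one of eight colonization
classes determined by its presence pattern across the three samples;
the class of interest is the *colonizer*: present in the donor and in
the recipient after FMT, but absent from the recipient before FMT.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tolerance on "rows sum to one" for relative tables
_REL_TOL = 1e-9
#: row sums above 1 + this flag a table as raw counts
_COUNT_TOL = 1e-6

STATUS_COLONIZER = "colonizer"
STATUS_RESIDENT_RETAINED = "resident_retained"
STATUS_RESIDENT_LOST = "resident_lost"
STATUS_RECIPIENT_UNIQUE_RETAINED = "recipient_unique_retained"
STATUS_REJECTED_DONOR = "rejected_donor"
STATUS_NOVEL_ACQUISITION = "novel_acquisition"
STATUS_TRANSIENT = "transient"
STATUS_ABSENT = "absent"

#: presence bits (donor, pre, post) -> colonization status
STATUS_BY_BITS: Mapping[tuple[int, int, int], str] = {
    (1, 0, 1): STATUS_COLONIZER,
    (1, 1, 1): STATUS_RESIDENT_RETAINED,
    (0, 1, 0): STATUS_RESIDENT_LOST,
    (0, 1, 1): STATUS_RECIPIENT_UNIQUE_RETAINED,
    (1, 0, 0): STATUS_REJECTED_DONOR,
    (0, 0, 1): STATUS_NOVEL_ACQUISITION,
    (1, 1, 0): STATUS_TRANSIENT,
    (0, 0, 0): STATUS_ABSENT,
}

ALL_STATUSES = tuple(STATUS_BY_BITS.values())


class TableError(ValueError):
    """Malformed abundance table or metadata."""


class ConfigurationError(ValueError):
    """A required input (e.g. read depths) is unavailable."""


@dataclass
class AbundanceTable:
    """A samples x taxa abundance matrix plus per-sample metadata.

    ``values`` holds non-negative reals with samples as rows.  When
    ``is_relative`` each row is closed to sum 1.  ``sample_meta`` is
    indexed by sample id with optional ``read_depth`` and ``study_id``
    columns; ``taxon_meta`` optionally carries lineage labels
    (phylum ... genus) indexed by taxon id.
    """

    values: pd.DataFrame
    is_relative: bool = False
    sample_meta: pd.DataFrame | None = None
    taxon_meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        if self.sample_meta is None:
            self.sample_meta = pd.DataFrame(index=self.values.index)
        self.validate()

    def validate(self) -> None:
        vals = self.values
        if vals.index.duplicated().any():
            dups = vals.index[vals.index.duplicated()].unique().tolist()
            raise TableError(f"duplicate sample ids: {dups}")
        if vals.columns.duplicated().any():
            dups = vals.columns[vals.columns.duplicated()].unique().tolist()
            raise TableError(f"duplicate taxon ids: {dups}")
        arr = vals.to_numpy(dtype=float)
        if arr.size and (arr < 0).any():
            row, col = np.argwhere(arr < 0)[0]
            raise TableError(
                f"negative abundance for sample {vals.index[row]!r}, "
                f"taxon {vals.columns[col]!r}"
            )
        if self.is_relative and arr.size:
            sums = arr.sum(axis=1)
            bad = np.flatnonzero(np.abs(sums - 1.0) > _REL_TOL)
            if bad.size:
                raise TableError(
                    f"relative table rows do not sum to 1: "
                    f"{vals.index[bad[:5]].tolist()}"
                )

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def taxon_ids(self) -> pd.Index:
        return self.values.columns

    def read_depths(self) -> pd.Series | None:
        """Per-sample read depth, from metadata or raw-count row sums."""
        meta = self.sample_meta
        if meta is not None and "read_depth" in meta.columns:
            depths = meta["read_depth"]
            if depths.notna().all():
                return depths.astype(float)
        if not self.is_relative:
            return self.values.sum(axis=1)
        return None


@dataclass(frozen=True)
class Triad:
    """One FMT experiment: donor, recipient-pre and recipient-post samples."""

    experiment_id: str
    donor_sample: str
    pre_sample: str
    post_sample: str
    subject_id: str
    donor_id: str
    study_id: str
    timepoint: int = 1

    def __post_init__(self) -> None:
        samples = {self.donor_sample, self.pre_sample, self.post_sample}
        if len(samples) != 3:
            raise TableError(
                f"triad {self.experiment_id!r} reuses a sample id: "
                f"{self.donor_sample}, {self.pre_sample}, {self.post_sample}"
            )


@dataclass
class ColonizationProfile:
    """Per-experiment mapping of every taxon to its colonization status."""

    experiment_id: str
    status: dict[str, str] = field(default_factory=dict)

    def taxa_with_status(self, status: str) -> list[str]:
        return [t for t, s in self.status.items() if s == status]

    @property
    def colonizers(self) -> list[str]:
        return self.taxa_with_status(STATUS_COLONIZER)


def read_abundance_table(path: str | Path, format: str = "tsv") -> AbundanceTable:
    """Read a taxa x samples table from TSV (or BIOM) into an AbundanceTable.

    The TSV layout is the common wide export: first column ``taxon_id``,
    remaining columns sample ids.  Rows become table columns (taxa) after
    transposition.  A table whose sample sums exceed 1 is flagged as raw
    counts (``is_relative=False``) and its row sums recorded as read depths.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "biom":
        return _read_biom(path)
    if format != "tsv":
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'biom'")
    raw = pd.read_csv(path, sep="\t", index_col=0)
    if raw.index.name is None and raw.empty:
        raise TableError(f"{path}: malformed header")
    try:
        raw = raw.astype(float)
    except (TypeError, ValueError) as exc:
        raise TableError(f"{path}: non-numeric abundance cell ({exc})") from exc
    values = raw.T  # samples x taxa
    values.index.name = "sample_id"
    values.columns.name = "taxon_id"
    return _table_from_values(values)


def _read_biom(path: Path) -> AbundanceTable:
    try:
        import biom
    except ImportError as exc:  # pragma: no cover - env dependent
        raise ConfigurationError(
            "BIOM input requires the 'biom-format' package; install it or "
            "convert the table to TSV (taxa as rows, samples as columns)."
        ) from exc
    bt = biom.load_table(str(path))
    frame = bt.to_dataframe(dense=True)  # observations (taxa) x samples
    values = frame.T.astype(float)
    values.index.name = "sample_id"
    values.columns.name = "taxon_id"
    return _table_from_values(values)


def _table_from_values(values: pd.DataFrame) -> AbundanceTable:
    """Classify freshly read values as counts or relative abundances.

    A table whose sample sums never exceed 1 (plus tolerance) is taken as
    relative and re-closed exactly, so round-tripping through finite-
    precision TSV keeps the sums-to-one invariant; otherwise the sums are
    recorded as read depths.
    """
    arr = values.to_numpy(dtype=float)
    if arr.size and (arr < 0).any():
        row, col = np.argwhere(arr < 0)[0]
        raise TableError(f"negative abundance for sample "
                         f"{values.index[row]!r}, taxon {values.columns[col]!r}")
    sums = values.sum(axis=1)
    is_relative = bool(len(values) > 0 and (sums <= 1.0 + _COUNT_TOL).all())
    meta = pd.DataFrame(index=values.index)
    if is_relative:
        zero = sums[sums <= 0]
        if len(zero):
            raise TableError(f"all-zero sample(s): {zero.index.tolist()}")
        values = values.div(sums, axis=0)
    else:
        meta["read_depth"] = sums
    return AbundanceTable(values=values, is_relative=is_relative,
                          sample_meta=meta)


def filter_samples(table: AbundanceTable, min_reads: int = 2000) -> AbundanceTable:
    """Drop samples sequenced to fewer than ``min_reads`` reads.

    The boundary is inclusive on the survivor side: a sample with exactly
    ``min_reads`` reads is kept.
    """
    depths = table.read_depths()
    if depths is None:
        raise ConfigurationError(
            "cannot filter by read depth: the table is relative and no "
            "'read_depth' column is present in sample_meta; supply depths "
            "or skip sample filtering"
        )
    keep = depths >= min_reads
    if not keep.any():
        logger.warning("filter_samples: all %d samples below min_reads=%d",
                       len(keep), min_reads)
    values = table.values.loc[keep[keep].index]
    meta = table.sample_meta.loc[values.index]
    return AbundanceTable(values=values, is_relative=table.is_relative,
                          sample_meta=meta, taxon_meta=table.taxon_meta)


def normalize_relative(table: AbundanceTable) -> AbundanceTable:
    """Close every sample to sum 1 (idempotent)."""
    sums = table.values.sum(axis=1)
    zero = sums[sums <= 0]
    if len(zero):
        raise TableError(f"all-zero sample(s): {zero.index.tolist()}")
    values = table.values.div(sums, axis=0)
    meta = table.sample_meta.copy()
    if "read_depth" not in meta.columns and not table.is_relative:
        meta["read_depth"] = sums
    return AbundanceTable(values=values, is_relative=True,
                          sample_meta=meta, taxon_meta=table.taxon_meta)


def filter_taxa(table: AbundanceTable, min_abundance: float = 0.0005,
                min_prevalence: float = 0.05) -> AbundanceTable:
    """Keep taxa whose relative abundance exceeds ``min_abundance`` in at
    least ``ceil(min_prevalence * n_samples)`` samples, then re-close rows.

    Both thresholds follow strict-greater semantics on abundance and an
    at-least (ceiling) rule on prevalence.
    """
    if not 0 <= min_abundance < 1:
        raise ValueError(f"min_abundance must lie in [0, 1); got {min_abundance}")
    if not table.is_relative:
        raise ConfigurationError("normalize to relative abundance before filter_taxa")
    n_samples = len(table.values)
    n_required = max(int(math.ceil(min_prevalence * n_samples)), 0)
    hits = (table.values > min_abundance).sum(axis=0)
    keep = hits >= n_required if n_required > 0 else hits > 0
    values = table.values.loc[:, keep[keep].index]
    sums = values.sum(axis=1)
    nonempty = sums > 0
    if not nonempty.all():
        dropped = sums.index[~nonempty].tolist()
        logger.warning("filter_taxa: dropping %d now-empty sample(s): %s",
                       len(dropped), dropped[:5])
        values = values.loc[nonempty]
        sums = sums[nonempty]
    values = values.div(sums, axis=0) if len(values) else values
    taxon_meta = None
    if table.taxon_meta is not None:
        taxon_meta = table.taxon_meta.loc[table.taxon_meta.index.intersection(values.columns)]
    return AbundanceTable(values=values, is_relative=True,
                          sample_meta=table.sample_meta.loc[values.index],
                          taxon_meta=taxon_meta)


def assemble_triads(metadata: pd.DataFrame, table: AbundanceTable) -> list[Triad]:
    """Build one Triad per metadata row, skipping rows that reference
    samples missing from the table (logged, not fatal).

    Expected columns: donor_sample, pre_sample, post_sample, subject_id,
    donor_id, study_id, timepoint; experiment_id is optional and defaults
    to ``<subject_id>:<post_sample>``.
    """
    required = {"donor_sample", "pre_sample", "post_sample",
                "subject_id", "donor_id", "study_id"}
    missing = required - set(metadata.columns)
    if missing:
        raise TableError(f"triad metadata missing columns: {sorted(missing)}")
    known = set(table.sample_ids)
    triads: list[Triad] = []
    for _, row in metadata.iterrows():
        samples = [row["donor_sample"], row["pre_sample"], row["post_sample"]]
        absent = [s for s in samples if s not in known]
        if absent:
            logger.warning("assemble_triads: skipping row for subject %r: "
                           "missing sample(s) %s", row["subject_id"], absent)
            continue
        exp_id = row.get("experiment_id")
        if exp_id is None or (isinstance(exp_id, float) and np.isnan(exp_id)):
            exp_id = f"{row['subject_id']}:{row['post_sample']}"
        triads.append(Triad(
            experiment_id=str(exp_id),
            donor_sample=str(row["donor_sample"]),
            pre_sample=str(row["pre_sample"]),
            post_sample=str(row["post_sample"]),
            subject_id=str(row["subject_id"]),
            donor_id=str(row["donor_id"]),
            study_id=str(row["study_id"]),
            timepoint=int(row.get("timepoint", 1)),
        ))
    ids = [t.experiment_id for t in triads]
    if len(set(ids)) != len(ids):
        raise TableError("duplicate experiment ids after triad assembly")
    return triads


def classify_colonization(triad: Triad, table: AbundanceTable) -> ColonizationProfile:
    """Assign each taxon its colonization status from presence bits.

    Presence is strictly positive abundance; zeros are treated as true
    absences.  The classification therefore only depends on the support of
    the three samples, never on abundance magnitudes.
    """
    donor = table.values.loc[triad.donor_sample] > 0
    pre = table.values.loc[triad.pre_sample] > 0
    post = table.values.loc[triad.post_sample] > 0
    status = {
        taxon: STATUS_BY_BITS[(int(d), int(p), int(o))]
        for taxon, d, p, o in zip(table.taxon_ids, donor, pre, post)
    }
    return ColonizationProfile(experiment_id=triad.experiment_id, status=status)


def colonization_summary(triads: Iterable[Triad], table: AbundanceTable,
                         profiles: Mapping[str, ColonizationProfile] | None = None,
                         ) -> pd.DataFrame:
    """Per-experiment colonizer counts and abundance statistics.

    Columns: ``n_colonizers``, ``colonizer_abundance_fraction`` (summed
    post-FMT relative abundance of colonizers), ``fraction_ge_twofold_change``
    (share of colonizers whose post/donor relative-abundance ratio is >= 2
    or <= 0.5) and ``no_colonizers`` flag.
    """
    records = []
    for triad in triads:
        profile = (profiles or {}).get(triad.experiment_id) \
            or classify_colonization(triad, table)
        colonizers = profile.colonizers
        rec = {"experiment_id": triad.experiment_id,
               "n_colonizers": len(colonizers),
               "colonizer_abundance_fraction": 0.0,
               "fraction_ge_twofold_change": 0.0,
               "no_colonizers": len(colonizers) == 0}
        if colonizers:
            post = table.values.loc[triad.post_sample, colonizers]
            donor = table.values.loc[triad.donor_sample, colonizers]
            ratio = post / donor
            rec["colonizer_abundance_fraction"] = float(post.sum())
            rec["fraction_ge_twofold_change"] = float(
                ((ratio >= 2.0) | (ratio <= 0.5)).mean())
        records.append(rec)
    return pd.DataFrame.from_records(records).set_index("experiment_id")


def prep_pipeline(table: AbundanceTable, metadata: pd.DataFrame,
                  min_reads: int | None = 2000, min_abundance: float = 0.0005,
                  min_prevalence: float = 0.05, per_study: bool = True,
                  ) -> tuple[AbundanceTable, list[Triad], dict[str, ColonizationProfile]]:
    """Standard preprocessing: filter samples -> normalize -> filter taxa ->
    re-normalize -> assemble triads -> classify colonization.

    The taxon prevalence filter is applied within each study by default
    (``per_study``); taxa passing in any study are retained globally.
    """
    if min_reads is not None:
        if table.read_depths() is None:
            logger.warning("prep_pipeline: no read depths available; "
                           "skipping the sample depth filter")
        else:
            table = filter_samples(table, min_reads=min_reads)
    table = normalize_relative(table)
    if per_study and "study_id" in table.sample_meta.columns:
        keep: set[str] = set()
        for _, ids in table.sample_meta.groupby("study_id").groups.items():
            sub = AbundanceTable(values=table.values.loc[ids],
                                 is_relative=True,
                                 sample_meta=table.sample_meta.loc[ids])
            filt = filter_taxa(sub, min_abundance, min_prevalence)
            keep |= set(filt.taxon_ids)
        values = table.values.loc[:, sorted(keep)]
        table = AbundanceTable(values=values, is_relative=False,
                               sample_meta=table.sample_meta,
                               taxon_meta=table.taxon_meta)
        table = normalize_relative(table)
        if table.taxon_meta is not None:
            table.taxon_meta = table.taxon_meta.loc[
                table.taxon_meta.index.intersection(table.values.columns)]
    else:
        table = filter_taxa(table, min_abundance, min_prevalence)
    triads = assemble_triads(metadata, table)
    profiles = {t.experiment_id: classify_colonization(t, table) for t in triads}
    return table, triads, profiles


def write_abundance_tsv(table: AbundanceTable, path: str | Path) -> None:
    """Write the table back in the wide taxa x samples TSV layout."""
    out = table.values.T
    out.index.name = "taxon_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def profiles_to_frame(profiles: Mapping[str, ColonizationProfile]) -> pd.DataFrame:
    """Long-format (experiment_id, taxon_id, status) frame for serialization."""
    rows = [(eid, taxon, status)
            for eid, prof in profiles.items()
            for taxon, status in prof.status.items()]
    return pd.DataFrame(rows, columns=["experiment_id", "taxon_id", "status"])
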