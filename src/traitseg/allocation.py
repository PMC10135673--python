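"""Fuzzy-coded trait allocation.

Taxon counts are translated into trait abundances through fuzzy affinity
scores.  Each taxon carries, per grouping feature (feeding style, respiration
mode, ...), an integer affinity score from 0 ("no affinity") to 5 ("high
affinity") for every trait in that feature.  Scores are normalised into
allocation coefficients in [0, 1] summing to one, the taxon's count is split
across traits proportionally, each share is rounded to the nearest whole
number, and shares are summed over all taxa present at a site.

A taxon may instead be flagged *uncoded* for a feature: no graded scores are
available, only the list of traits it possesses, and its count is split
equally among those traits (e.g. a coefficient of 0.5 each for two traits).
"Uncoded" is distinct from "coded with all-zero affinities"; the latter
contributes nothing to the feature.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._catalog import MAX_AFFINITY
from .errors import ValidationError

__all__ = [
    "TraitAffinityTable",
    "TraitAbundanceMatrix",
    "affinities_to_coefficients",
    "allocate_taxon_abundance",
    "build_trait_abundance_matrix",
    "filter_sparse_traits",
    "round_half_away",
    "validate_taxa_counts",
]


def round_half_away(values: np.ndarray) -> np.ndarray:
    """Round to the nearest whole number, ties away from zero.

    This is the single, swappable rounding rule used everywhere a fractional
    trait share becomes an integer abundance.  ``numpy.round`` is *not* used
    because it rounds ties to even.
    """
    values = np.asarray(values, dtype=float)
    return (np.sign(values) * np.floor(np.abs(values) + 0.5)).astype(np.int64)


def affinities_to_coefficients(
    affinities: np.ndarray | list,
    coded: bool = True,
    *,
    taxon: str = "?",
    feature: str = "?",
) -> np.ndarray:
    """Normalise one taxon's affinity scores for one grouping feature into
    allocation coefficients.

    Parameters
    ----------
    affinities
        Integer scores in {0, ..., 5}, one per trait of the feature.  For an
        *uncoded* taxon the nonzero entries mark the traits the taxon is
        recorded to possess (their magnitude is ignored).
    coded
        True if the taxon has fuzzy information for this feature.

    Returns
    -------
    ndarray
        Coefficients in [0, 1] summing to 1, or an all-zero vector when a
        coded taxon has no affinity for any trait of the feature.
    """
    a = np.asarray(affinities, dtype=float)
    if a.ndim != 1 or a.size < 1:
        raise ValidationError(
            f"affinity vector for taxon {taxon!r}, feature {feature!r} must be 1-D and non-empty"
        )
    if np.any(~np.isfinite(a)) or np.any(a != np.floor(a)) or np.any(a < 0) or np.any(a > MAX_AFFINITY):
        bad = [i for i, v in enumerate(a) if not (np.isfinite(v) and v == np.floor(v) and 0 <= v <= MAX_AFFINITY)]
        raise ValidationError(
            f"taxon {taxon!r}, feature {feature!r}: affinity scores must be integers in "
            f"[0, {MAX_AFFINITY}]; offending trait positions {bad}"
        )
    if coded:
        total = a.sum()
        if total == 0:
            return np.zeros_like(a)
        return a / total
    # equal-coding fallback for uncoded taxa
    possessed = a > 0
    n = int(possessed.sum())
    if n == 0:
        return np.zeros_like(a)
    out = np.zeros_like(a)
    out[possessed] = 1.0 / n
    return out


def allocate_taxon_abundance(count: int, coefficients: np.ndarray) -> np.ndarray:
    """Split one taxon's count across traits: ``round(count * c_t)`` per trait
    with ties rounded away from zero."""
    if count < 0 or count != int(count):
        raise ValidationError(f"taxon count must be a non-negative integer, got {count!r}")
    c = np.asarray(coefficients, dtype=float)
    if np.any(c < 0) or np.any(c > 1):
        raise ValidationError("allocation coefficients must lie in [0, 1]")
    s = c.sum()
    if s > 0 and abs(s - 1.0) > 1e-12:
        raise ValidationError(f"allocation coefficients must sum to 1 or 0, got {s!r}")
    return round_half_away(int(count) * c)


@dataclass
class TraitAffinityTable:
    """Taxon x trait fuzzy affinity scores, organised by grouping feature.

    Attributes
    ----------
    scores
        DataFrame indexed by taxon with a two-level column index
        ``(grouping_feature, trait)`` and integer cells in {0, ..., 5}.
    uncoded
        Mapping ``(taxon, feature) -> tuple of possessed trait names`` for the
        taxon/feature pairs that lack fuzzy coding.  Any pair not listed is
        treated as coded.
    """

    scores: pd.DataFrame
    uncoded: dict[tuple[str, str], tuple[str, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not isinstance(self.scores.columns, pd.MultiIndex) or self.scores.columns.nlevels != 2:
            raise ValidationError("affinity scores need a (grouping_feature, trait) column MultiIndex")
        vals = self.scores.to_numpy(dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals != np.floor(vals)) or vals.min(initial=0) < 0 or vals.max(initial=0) > MAX_AFFINITY:
            r, c = np.argwhere(~((vals >= 0) & (vals <= MAX_AFFINITY) & (vals == np.floor(vals))))[0]
            raise ValidationError(
                f"taxon {self.scores.index[r]!r}, trait {self.scores.columns[c]!r}: "
                f"affinity must be an integer in [0, {MAX_AFFINITY}]"
            )
        traits = self.scores.columns.get_level_values(1)
        if traits.duplicated().any():
            dup = traits[traits.duplicated()].tolist()
            raise ValidationError(f"traits must belong to exactly one grouping feature; duplicated: {dup}")
        self.scores = self.scores.astype(np.int64)

    @property
    def features(self) -> list[str]:
        return list(self.scores.columns.get_level_values(0).unique())

    @property
    def taxa(self) -> list[str]:
        return list(self.scores.index)

    def is_coded(self, taxon: str, feature: str) -> bool:
        return (taxon, feature) not in self.uncoded

    def coefficients(self, taxon: str, feature: str) -> np.ndarray:
        """Allocation coefficients for one taxon over one feature's traits."""
        block = self.scores.loc[taxon, feature]
        traits = list(block.index)
        if self.is_coded(taxon, feature):
            return affinities_to_coefficients(block.to_numpy(), True, taxon=taxon, feature=feature)
        possessed = self.uncoded[(taxon, feature)]
        unknown = set(possessed) - set(traits)
        if unknown:
            raise ValidationError(f"taxon {taxon!r}: possessed traits {sorted(unknown)} not in feature {feature!r}")
        indicator = np.array([1 if t in possessed else 0 for t in traits], dtype=float)
        return affinities_to_coefficients(indicator, False, taxon=taxon, feature=feature)

    def coefficient_frame(self) -> pd.DataFrame:
        """All coefficients as a taxon x (feature, trait) DataFrame (cached)."""
        cached = getattr(self, "_coef_cache", None)
        if cached is not None:
            return cached
        out = pd.DataFrame(0.0, index=self.scores.index, columns=self.scores.columns)
        for taxon in self.taxa:
            for feature in self.features:
                out.loc[taxon, feature] = self.coefficients(taxon, feature)
        object.__setattr__(self, "_coef_cache", out)
        return out

    # -- CSV dialect: one column per trait named "<feature>::<trait>", plus an
    # optional sidecar column "uncoded::<feature>" holding a ';'-separated list
    # of possessed traits for taxa without fuzzy coding of that feature.

    @classmethod
    def from_csv(cls, path) -> "TraitAffinityTable":
        raw = pd.read_csv(path, index_col=0)
        score_cols = [c for c in raw.columns if "::" in c and not c.startswith("uncoded::")]
        uncoded_cols = [c for c in raw.columns if c.startswith("uncoded::")]
        pairs = [tuple(c.split("::", 1)) for c in score_cols]
        scores = raw[score_cols].fillna(0)
        scores.columns = pd.MultiIndex.from_tuples(pairs, names=["feature", "trait"])
        uncoded: dict[tuple[str, str], tuple[str, ...]] = {}
        for col in uncoded_cols:
            feature = col.split("::", 1)[1]
            for taxon, cell in raw[col].items():
                if isinstance(cell, str) and cell.strip():
                    uncoded[(str(taxon), feature)] = tuple(t.strip() for t in cell.split(";") if t.strip())
        return cls(scores=scores, uncoded=uncoded)

    def to_csv(self, path) -> None:
        flat = self.scores.copy()
        flat.columns = [f"{f}::{t}" for f, t in self.scores.columns]
        for feature in self.features:
            col = f"uncoded::{feature}"
            flat[col] = ""
            for (taxon, feat), possessed in self.uncoded.items():
                if feat == feature:
                    flat.loc[taxon, col] = ";".join(possessed)
        flat.index.name = "taxon"
        flat.to_csv(path)


def validate_taxa_counts(taxa: pd.DataFrame) -> pd.DataFrame:
    """Check the long-format (site_id, taxon, count) table contract."""
    missing = {"site_id", "taxon", "count"} - set(taxa.columns)
    if missing:
        raise ValidationError(f"taxa count table lacks columns: {sorted(missing)}")
    counts = taxa["count"]
    if counts.isna().any() or (counts < 0).any() or (counts != counts.astype(np.int64)).any():
        raise ValidationError("taxa counts must be non-negative integers")
    dup = taxa.duplicated(subset=["site_id", "taxon"])
    if dup.any():
        pairs = taxa.loc[dup, ["site_id", "taxon"]].to_records(index=False).tolist()
        raise ValidationError(f"duplicate (site_id, taxon) records: {pairs[:5]}")
    return taxa


@dataclass
class TraitAbundanceMatrix:
    """Site x trait integer abundances with per-trait exclusion flags.

    ``data`` is indexed by site with the same (feature, trait) column
    MultiIndex as the affinity table; ``excluded`` marks traits dropped by the
    sparsity filter (data are preserved, flags only).
    """

    data: pd.DataFrame
    excluded: pd.Series | None = None

    def __post_init__(self) -> None:
        vals = self.data.to_numpy()
        if np.any(vals < 0):
            raise ValidationError("trait abundances must be non-negative")
        self.data = self.data.astype(np.int64)
        if self.excluded is None:
            self.excluded = pd.Series(False, index=self.data.columns)

    @property
    def sites(self) -> list:
        return list(self.data.index)

    def retained(self) -> pd.DataFrame:
        """The abundance sub-matrix for traits not flagged excluded."""
        return self.data.loc[:, ~self.excluded]

    def exclusion_report(self) -> pd.DataFrame:
        zero_frac = (self.data == 0).mean(axis=0)
        return pd.DataFrame(
            {
                "feature": self.data.columns.get_level_values(0),
                "trait": self.data.columns.get_level_values(1),
                "zero_fraction": zero_frac.to_numpy(),
                "excluded": self.excluded.to_numpy(),
            }
        )

    def to_csv(self, path) -> None:
        flat = self.data.copy()
        flat.columns = [f"{f}::{t}" for f, t in self.data.columns]
        flat.index.name = "site_id"
        flat.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "TraitAbundanceMatrix":
        raw = pd.read_csv(path, index_col=0)
        raw.columns = pd.MultiIndex.from_tuples(
            [tuple(c.split("::", 1)) for c in raw.columns], names=["feature", "trait"]
        )
        return cls(data=raw)


def build_trait_abundance_matrix(
    taxa: pd.DataFrame,
    affinity: TraitAffinityTable,
    *,
    on_unknown: str = "error",
) -> TraitAbundanceMatrix:
    """Allocate every taxon record and sum trait shares per site.

    Rounding happens per taxon *before* summation across taxa.  Sites with no
    records yield all-zero rows.

    Parameters
    ----------
    on_unknown
        ``"error"`` (default): a taxon absent from the affinity table aborts
        with the full list of missing taxa.  ``"skip"``: such records are
        dropped (their taxa reported in the matrix's ``skipped_taxa``
        attribute).
    """
    taxa = validate_taxa_counts(taxa)
    if on_unknown not in ("error", "skip"):
        raise ValidationError(f"on_unknown must be 'error' or 'skip', got {on_unknown!r}")
    known = set(affinity.taxa)
    present = set(taxa["taxon"].unique())
    unknown = sorted(present - known)
    if unknown and on_unknown == "error":
        raise ValidationError(f"taxa missing from the affinity table: {unknown}")

    coef = affinity.coefficient_frame()
    sites = pd.Index(pd.unique(taxa["site_id"]), name="site_id")
    records = taxa[taxa["taxon"].isin(known)] if unknown else taxa
    # per-record rounded shares, then summed per site (rounding precedes summation)
    taxon_idx = coef.index.get_indexer(records["taxon"])
    site_idx = sites.get_indexer(records["site_id"])
    shares = round_half_away(
        records["count"].to_numpy(dtype=float)[:, None] * coef.to_numpy()[taxon_idx]
    )
    totals = np.zeros((len(sites), coef.shape[1]), dtype=np.int64)
    np.add.at(totals, site_idx, shares)
    grid = pd.DataFrame(totals, index=sites, columns=affinity.scores.columns)
    out = TraitAbundanceMatrix(data=grid)
    out.skipped_taxa = unknown  # type: ignore[attr-defined]
    return out


def filter_sparse_traits(
    matrix: TraitAbundanceMatrix,
    max_zero_fraction: float = 0.9,
    *,
    exclude: list[tuple[str, str]] | None = None,
) -> TraitAbundanceMatrix:
    """Flag traits that are zero at too many sites.

    A trait whose fraction of zero-abundance sites *exceeds*
    ``max_zero_fraction`` is flagged excluded; the data are preserved.  An
    explicit ``exclude`` list of (feature, trait) pairs is applied on top,
    to reproduce a fixed exclusion set exactly.
    """
    if not (0 < max_zero_fraction <= 1):
        raise ValidationError(f"max_zero_fraction must be in (0, 1], got {max_zero_fraction}")
    zero_frac = (matrix.data == 0).mean(axis=0)
    flags = zero_frac > max_zero_fraction
    if exclude:
        for pair in exclude:
            if pair not in matrix.data.columns:
                raise ValidationError(f"explicit exclusion {pair!r} is not a trait column")
            flags.loc[pair] = True
    return TraitAbundanceMatrix(data=matrix.data.copy(), excluded=flags)
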