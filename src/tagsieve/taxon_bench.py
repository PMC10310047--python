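"""Taxonomic benchmarking: stringency filtering, relative abundance,
mean-squared-error scoring against a known composition, and misassignment
rates.

Input is a peptide→taxon assignment table in the shape of a pept2lca export
(one row per peptide per taxonomic level, with peptide and MS/MS counts);
computing lowest common ancestors is out of scope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Dict, Iterable, Mapping, Optional, Set, Union

import pandas as pd

logger = logging.getLogger(__name__)

#: Default stringency: keep taxa representing strictly more than this
#: percentage of characterised counts, applied separately per level.
DEFAULT_STRINGENCY_PERCENT = 0.5

LEVELS = ("species", "genus", "family", "phylum", "kingdom", "superkingdom",
          "taxon_name")

ASSIGNMENT_COLUMNS = ["peptide", "level", "taxon", "peptide_count", "msms_count"]


@dataclass
class TaxonProfile:
    """Aggregated counts per taxon at one taxonomic level.

    ``total`` is the sum of the current counts; ``source_total`` preserves
    the pre-filter denominator so percentages stay relative to all
    characterised counts (including later-dropped or misassigned taxa).
    """

    level: str
    counts: Dict[str, int]
    source_total: Optional[int] = None

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def denominator(self) -> int:
        return self.source_total if self.source_total is not None else self.total


def load_assignments(source: Union[str, Path, IO[str]]) -> pd.DataFrame:
    """Read a tab-separated assignment table (peptide, level, taxon,
    peptide_count, msms_count)."""
    df = pd.read_csv(source, sep="\t", dtype={"peptide": str, "level": str,
                                              "taxon": str})
    missing = [c for c in ASSIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"assignment table missing columns: {missing}")
    for col in ("peptide_count", "msms_count"):
        if (df[col] < 0).any():
            raise ValueError(f"negative values in column {col!r}")
    return df


def profile_from_assignments(
    assignments: pd.DataFrame,
    level: str,
    weight: str = "msms_count",
    relabel: Optional[Mapping[str, str]] = None,
) -> TaxonProfile:
    """Aggregate counts per taxon at one level.

    ``relabel`` applies an explicit taxon→taxon mapping before aggregation
    (e.g. merging congeneric species onto a genus-level label).
    """
    sub = assignments[assignments["level"] == level]
    counts: Dict[str, int] = {}
    for taxon, n in zip(sub["taxon"], sub[weight]):
        if relabel:
            taxon = relabel.get(taxon, taxon)
        counts[taxon] = counts.get(taxon, 0) + int(n)
    return TaxonProfile(level=level, counts=counts)


def stringency_filter(profile: TaxonProfile,
                      threshold_percent: float = DEFAULT_STRINGENCY_PERCENT
                      ) -> TaxonProfile:
    """Drop spurious taxa: retain exactly those strictly above the threshold
    percentage of the profile's denominator.

    The original total is preserved as ``source_total`` so downstream
    percentages remain relative to all characterised counts.  Idempotent at
    a fixed denominator; never increases the taxon count.
    """
    denom = profile.denominator
    if denom == 0:
        logger.warning("stringency filter on empty profile (total 0)")
        return TaxonProfile(level=profile.level, counts={}, source_total=0)
    kept = {t: c for t, c in profile.counts.items()
            if 100.0 * c / denom > threshold_percent}
    return TaxonProfile(level=profile.level, counts=kept, source_total=denom)


def relative_abundance(profile: TaxonProfile,
                       taxa: Optional[Iterable[str]] = None
                       ) -> Dict[str, float]:
    """Percentage of each taxon relative to total characterised counts.

    The denominator includes every characterised count — misassigned and
    filtered-out taxa included — so unexpected mass depresses the expected
    taxa's percentages.  Taxa absent from the profile report 0%.
    """
    denom = profile.denominator
    if denom == 0:
        raise ValueError("profile has zero total")
    names = list(taxa) if taxa is not None else sorted(profile.counts)
    return {t: 100.0 * profile.counts.get(t, 0) / denom for t in names}


def mse_score(observed: Mapping[str, float],
              expected: Mapping[str, float]) -> float:
    """Mean squared error of observed vs expected percentages over the
    expected taxa (missing observations default to 0%).  Closer to 0 means
    a more accurate representation of relative taxon abundance."""
    if not expected:
        raise ValueError("expected composition is empty")
    return sum((observed.get(t, 0.0) - e) ** 2 for t, e in expected.items()) / len(expected)


def misassignment_rate(profile: TaxonProfile,
                       expected_taxa: Set[str],
                       allowed_taxa: Optional[Set[str]] = None) -> float:
    """Percentage of counts assigned to taxa outside expected ∪ allowed.

    ``allowed_taxa`` models post-hoc whitelisting of plausible taxa (related
    strains, known contaminants); growing it can only lower the rate.
    """
    if profile.total == 0:
        raise ValueError("profile has zero total")
    ok = set(expected_taxa) | (set(allowed_taxa) if allowed_taxa else set())
    bad = sum(c for t, c in profile.counts.items() if t not in ok)
    return 100.0 * bad / profile.total


def load_ground_truth(source: Union[str, Path, IO[str]]
                      ) -> Dict[str, Dict[str, float]]:
    """Read a tab-separated ground-truth composition (level, taxon,
    expected_percent) into level → {taxon: percent}.  Percentages per level
    may sum to less than 100 (unassigned remainder allowed)."""
    df = pd.read_csv(source, sep="\t", dtype={"level": str, "taxon": str})
    for col in ("level", "taxon", "expected_percent"):
        if col not in df.columns:
            raise ValueError(f"ground-truth table missing column {col!r}")
    out: Dict[str, Dict[str, float]] = {}
    for row in df.itertuples(index=False):
        out.setdefault(row.level, {})[row.taxon] = float(row.expected_percent)
    for level, comp in out.items():
        if sum(comp.values()) > 100.0 + 1e-9:
            raise ValueError(f"expected percentages at level {level!r} exceed 100")
    return out
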