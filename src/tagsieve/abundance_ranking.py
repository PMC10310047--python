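"""NSAF abundance estimation and two-pass probabilistic database filtering.

Protein abundance is estimated by spectral counting: the number of mapped
MS/MS per sample is divided by protein length (SAF) and normalized so each
sample's values sum to 1 (NSAF).  NSAF summed across samples and divided by
the grand total gives a protein marginal probability P(Protein) — the chance
a randomly drawn mapped spectrum belongs to that protein.

Filtering is greedy and two-pass:

* pass 1 ranks by P(Protein) and keeps exactly the proteins contributing at
  least one spectrum unseen in any protein above them (a minimal covering
  set); sets of isoforms sharing an identical spectrum set collapse to the
  shortest member (highest NSAF);
* organism marginals P(Organism) are computed on the pass-1 retained set by
  aggregating summed NSAF per organism;
* pass 2 annotates the full unfiltered set with
  P(Organism, Protein) = P(Organism) × P(Protein) (conditional-independence
  assumption), re-ranks by this joint probability, and re-filters, yielding
  a minimal subset that still explains every mapped spectrum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Set, Tuple

from .sequence_db import ProteinRecord
from .tag_matcher import SpectralCounts
from .tag_store import SpectrumKey

logger = logging.getLogger(__name__)


@dataclass
class AbundanceRow:
    """Per-protein SAF/NSAF values and the protein marginal probability."""

    accession: str
    length: int
    saf: Dict[str, float]
    nsaf: Dict[str, float]
    nsaf_sum: float = 0.0
    p_protein: float = 0.0


@dataclass
class RankedProtein:
    accession: str
    p_protein: float
    p_organism: float = 0.0
    joint: float = 0.0
    rank: int = 0
    retained: bool = False
    unique_spectra: Set[SpectrumKey] = field(default_factory=set)
    # sort metadata (D13 tie-breaking)
    nsaf_sum: float = 0.0
    length: int = 0


def _all_spectra(per_sample: Mapping[str, Set[SpectrumKey]]) -> Set[SpectrumKey]:
    out: Set[SpectrumKey] = set()
    for spectra in per_sample.values():
        out |= spectra
    return out


def compute_abundance(counts: SpectralCounts,
                      lengths: Mapping[str, int]) -> List[AbundanceRow]:
    """SAF, per-sample NSAF, summed NSAF, and P(Protein) for every protein.

    ``lengths`` must cover every accession in ``counts``.  A sample whose
    total SAF is zero gets all-zero NSAF with a warning rather than failing.
    P(Protein) sums to 1 over the proteins (single protein ⇒ exactly 1).
    """
    samples = sorted({s for per in counts.values() for s in per})
    rows: List[AbundanceRow] = []
    for acc in sorted(counts):
        length = lengths[acc]
        saf = {s: len(counts[acc].get(s, ())) / length for s in samples}
        rows.append(AbundanceRow(accession=acc, length=length, saf=saf, nsaf={}))
    for s in samples:
        total = sum(row.saf[s] for row in rows)
        if total == 0.0:
            logger.warning("sample %r has zero total SAF; NSAF set to 0", s)
            for row in rows:
                row.nsaf[s] = 0.0
        else:
            for row in rows:
                row.nsaf[s] = row.saf[s] / total
    for row in rows:
        row.nsaf_sum = sum(row.nsaf.values())
    grand = sum(row.nsaf_sum for row in rows)
    for row in rows:
        row.p_protein = row.nsaf_sum / grand if grand > 0 else 0.0
        assert row.p_protein <= 1.0 + 1e-12  # normalization caps at 1
    return rows


def _tie_key(rp: RankedProtein) -> Tuple[float, int, str]:
    # descending nsaf_sum, then ascending length, then ascending accession
    return (-rp.nsaf_sum, rp.length, rp.accession)


def rank_by_protein(abundance: Sequence[AbundanceRow]) -> List[RankedProtein]:
    """Pass-1 ordering: descending P(Protein) with the deterministic
    tie-break (descending summed NSAF, ascending length, ascending
    accession)."""
    ranked = [
        RankedProtein(accession=row.accession, p_protein=row.p_protein,
                      nsaf_sum=row.nsaf_sum, length=row.length)
        for row in abundance
    ]
    ranked.sort(key=lambda rp: (-rp.p_protein,) + _tie_key(rp))
    for i, rp in enumerate(ranked, start=1):
        rp.rank = i
    return ranked


def greedy_filter(ranked: Sequence[RankedProtein],
                  counts: SpectralCounts) -> List[RankedProtein]:
    """Top-down minimal-set filter.

    Walking the ranked list, a protein is retained iff it contributes at
    least one spectrum not seen in any protein above its position; those
    spectra become its ``unique_spectra`` and all of its spectra join the
    seen set.  The retained set covers every spectrum mapping to at least
    one ranked protein.
    """
    seen: Set[SpectrumKey] = set()
    retained: List[RankedProtein] = []
    for rp in ranked:
        spectra = _all_spectra(counts.get(rp.accession, {}))
        unique = spectra - seen
        rp.unique_spectra = unique
        rp.retained = bool(unique)
        if rp.retained:
            retained.append(rp)
        seen |= spectra
    return retained


def organism_marginals(retained: Sequence[RankedProtein],
                       abundance: Sequence[AbundanceRow],
                       organisms: Mapping[str, str]) -> Dict[str, float]:
    """P(Organism): summed NSAF of the retained set aggregated by organism
    and divided by the retained total.  Organisms absent from the retained
    set implicitly carry probability 0."""
    nsaf_by_acc = {row.accession: row.nsaf_sum for row in abundance}
    sums: Dict[str, float] = {}
    for rp in retained:
        org = organisms.get(rp.accession, "unknown")
        sums[org] = sums.get(org, 0.0) + nsaf_by_acc[rp.accession]
    total = sum(sums.values())
    if total == 0.0:
        return {org: 0.0 for org in sums}
    return {org: v / total for org, v in sums.items()}


def joint_rank(abundance: Sequence[AbundanceRow],
               profile: Mapping[str, float],
               organisms: Mapping[str, str]) -> List[RankedProtein]:
    """Pass-2 ordering of the full unfiltered set by
    P(Organism, Protein) = P(Organism) × P(Protein).

    P(Protein) values are the pass-1 marginals (only the organism term is
    new).  Proteins of organisms absent from the pass-1 retained set carry a
    joint of 0 but stay in the list — they sort last and may still be
    retained if they alone explain spectra, preserving coverage.
    """
    ranked = []
    for row in abundance:
        org = organisms.get(row.accession, "unknown")
        p_org = profile.get(org, 0.0)
        ranked.append(RankedProtein(
            accession=row.accession,
            p_protein=row.p_protein,
            p_organism=p_org,
            joint=p_org * row.p_protein,
            nsaf_sum=row.nsaf_sum,
            length=row.length,
        ))
    ranked.sort(key=lambda rp: (-rp.joint,) + _tie_key(rp))
    for i, rp in enumerate(ranked, start=1):
        rp.rank = i
    return ranked


@dataclass
class TwoPassResult:
    abundance: List[AbundanceRow]
    pass1_ranked: List[RankedProtein]
    pass1_retained: List[RankedProtein]
    organism_profile: Dict[str, float]
    ranked: List[RankedProtein]          # pass-2 ordering, full set
    retained: List[RankedProtein]        # final minimal set


def run_two_pass(records: Sequence[ProteinRecord],
                 counts: SpectralCounts) -> TwoPassResult:
    """Full two-pass ranking and filtering from protein→spectra counts.

    The returned ``retained`` list is a minimal subset of the database that
    explains every mapped spectrum, in pass-2 rank order.
    """
    if not counts:
        logger.warning("no mapped spectra: filtered database is empty")
        return TwoPassResult([], [], [], {}, [], [])
    by_acc = {rec.accession: rec for rec in records}
    missing = [acc for acc in counts if acc not in by_acc]
    if missing:
        raise ValueError(f"counts reference unknown accessions: {missing[:5]}")
    lengths = {acc: by_acc[acc].length for acc in counts}
    organisms = {acc: by_acc[acc].organism for acc in counts}

    abundance = compute_abundance(counts, lengths)
    pass1_ranked = rank_by_protein(abundance)
    pass1_retained = greedy_filter(pass1_ranked, counts)
    profile = organism_marginals(pass1_retained, abundance, organisms)
    ranked = joint_rank(abundance, profile, organisms)
    retained = greedy_filter(ranked, counts)
    return TwoPassResult(
        abundance=abundance,
        pass1_ranked=pass1_ranked,
        pass1_retained=pass1_retained,
        organism_profile=profile,
        ranked=ranked,
        retained=retained,
    )
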