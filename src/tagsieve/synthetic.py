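"""Ground-truthed synthetic metaproteomes and noisy tag observations.

The generator emulates the pipeline's two inputs — a protein FASTA with
UniProt-style headers and a per-spectrum tag table — with a known ground
truth, so the whole workflow is testable end-to-end without downloads:

* a community of ``n_organisms`` organisms with Dirichlet-distributed
  abundance fractions, each contributing random tryptic proteins;
* distractor proteins from organisms never sampled (emulating the vast
  excess of irrelevant database entries);
* isoform pairs — duplicated proteins with one appended residue — to
  exercise the shortest-sequence collapse;
* per spectrum, a true tag read from a tryptic peptide of a sampled protein
  (flank masses are exact residue sums with fixed carbamidomethylation of C,
  plus Gaussian noise), with the remaining tag slots per spectrum filled by
  random decoy tags.  Tag letters are never corrupted: the noise model
  isolates the matcher's mass-tolerance logic.

Everything is bit-reproducible from ``config.seed``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .chem import CARBAMIDOMETHYL, MONOISOTOPIC, flank_mass
from .sequence_db import ProteinRecord
from .tag_matcher import SpectralCounts
from .tag_store import REQUIRED_COLUMNS, SpectrumKey

logger = logging.getLogger(__name__)

_FIXED = {"C": CARBAMIDOMETHYL}
_AA20 = np.array(sorted(MONOISOTOPIC), dtype="U1")
_SEGMENT_AA = np.array([a for a in sorted(MONOISOTOPIC) if a not in "KR"],
                       dtype="U1")


@dataclass
class SyntheticConfig:
    """Study conditions for a synthetic run.

    Defaults reproduce the benchmark community: 5 organisms with Dirichlet(1)
    abundance fractions, 2000 spectra across 2 samples, 5 tags of length 4
    per spectrum, gap noise sd 0.005 Da (inside the 0.02 Da tolerance), 20%
    decoy rank-1 tags, and a database dominated by 10000 distractor entries.
    """

    n_organisms: int = 5
    proteins_per_organism: int = 20
    protein_length_range: Tuple[int, int] = (120, 400)
    organism_abundance: float = 1.0     # Dirichlet concentration
    n_samples: int = 2
    n_spectra: int = 2000
    tags_per_spectrum: int = 5
    tag_length: int = 4
    gap_noise_sd: float = 0.005
    decoy_tag_fraction: float = 0.2
    decoy_gap_max: float = 500.0
    distractor_proteins: int = 10000
    isoform_pairs: int = 5
    max_missed_cleavages: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.tags_per_spectrum < 1 or self.tags_per_spectrum > 5:
            raise ValueError("tags_per_spectrum must be in 1..5")
        lo, hi = self.protein_length_range
        if lo > hi or lo < 3 * (self.tag_length + 2):
            raise ValueError(
                "protein_length_range too small to guarantee >=3 tryptic "
                f"peptides of length >= {self.tag_length + 2}"
            )
        if not 0.0 <= self.decoy_tag_fraction <= 1.0:
            raise ValueError("decoy_tag_fraction must be in [0,1]")
        if self.gap_noise_sd < 0:
            raise ValueError("gap_noise_sd must be >= 0")


@dataclass
class GroundTruth:
    """What the simulator knows: the answer key for recovery scoring."""

    organism_fractions: Dict[str, float]
    proteins_by_organism: Dict[str, List[str]]
    isoform_twin: Dict[str, str]        # accession <-> its duplicate, both ways
    # filled by simulate_tags:
    sources: Dict[SpectrumKey, Tuple[str, str, int]] = field(default_factory=dict)
    decoy_spectra: Set[SpectrumKey] = field(default_factory=set)
    sampled_accessions: Set[str] = field(default_factory=set)


def _random_protein(rng: np.random.Generator, length_range: Tuple[int, int],
                    tag_length: int) -> str:
    """Random sequence built from tryptic segments.

    Each segment is >= tag_length+1 non-K/R residues followed by K or R, so
    every fully tryptic peptide has length >= tag_length+2 and at least
    three segments exist.  Total length lands in (or just above) the range.
    """
    lo, hi = length_range
    target = int(rng.integers(lo, hi + 1))
    parts: List[str] = []
    total = 0
    while total < target or len(parts) < 3:
        interior = int(rng.integers(tag_length + 1, tag_length + 12))
        idx = rng.integers(0, len(_SEGMENT_AA), size=interior)
        terminator = "K" if rng.random() < 0.5 else "R"
        parts.append("".join(_SEGMENT_AA[idx]) + terminator)
        total += interior + 1
    return "".join(parts)


def generate_database(config: SyntheticConfig
                      ) -> Tuple[List[ProteinRecord], GroundTruth]:
    """Generate the protein database and the ground-truth skeleton.

    Deterministic under ``config.seed``: the same seed yields a
    byte-identical FASTA.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 0])
    records: List[ProteinRecord] = []
    proteins_by_organism: Dict[str, List[str]] = {}

    for i in range(1, config.n_organisms + 1):
        org = f"Organism_{i}"
        proteins_by_organism[org] = []
        for j in range(1, config.proteins_per_organism + 1):
            acc = f"O{i:02d}P{j:03d}"
            seq = _random_protein(rng, config.protein_length_range,
                                  config.tag_length)
            header = (f"tr|{acc}|{acc}_SYN Synthetic protein {j} "
                      f"OS={org} OX={9000 + i} GN=syn{j}")
            records.append(ProteinRecord(accession=acc, header=header,
                                         sequence=seq))
            proteins_by_organism[org].append(acc)

    isoform_twin: Dict[str, str] = {}
    true_records = list(records)
    n_pairs = min(config.isoform_pairs, len(true_records))
    for p in range(n_pairs):
        base = true_records[p]
        twin_acc = base.accession + "b"
        extra = str(_AA20[int(rng.integers(0, len(_AA20)))])
        header = (f"tr|{twin_acc}|{twin_acc}_SYN Synthetic isoform of "
                  f"{base.accession} OS={base.organism} OX={9000} GN=iso{p}")
        records.append(ProteinRecord(accession=twin_acc, header=header,
                                     sequence=base.sequence + extra))
        isoform_twin[base.accession] = twin_acc
        isoform_twin[twin_acc] = base.accession

    per_distractor_org = max(1, config.proteins_per_organism)
    for d in range(config.distractor_proteins):
        org = f"Distractor_{d // per_distractor_org + 1}"
        acc = f"DX{d:06d}"
        seq = _random_protein(rng, config.protein_length_range,
                              config.tag_length)
        header = (f"tr|{acc}|{acc}_SYN Synthetic distractor OS={org} "
                  f"OX={80000 + d // per_distractor_org}")
        records.append(ProteinRecord(accession=acc, header=header,
                                     sequence=seq))

    if config.organism_abundance <= 0:
        raise ValueError("organism_abundance concentration must be > 0")
    fractions = rng.dirichlet(
        np.full(config.n_organisms, float(config.organism_abundance)))
    organism_fractions = {
        f"Organism_{i + 1}": float(fractions[i]) for i in range(config.n_organisms)
    }
    truth = GroundTruth(organism_fractions=organism_fractions,
                        proteins_by_organism=proteins_by_organism,
                        isoform_twin=isoform_twin)
    return records, truth


def tryptic_peptides(sequence: str, max_missed: int = 2,
                     min_length: int = 1) -> List[Tuple[int, int]]:
    """Fully tryptic (start, end) windows with <= max_missed internal K/R."""
    cuts = [0] + [i + 1 for i, ch in enumerate(sequence) if ch in "KR"]
    if cuts[-1] != len(sequence):
        cuts.append(len(sequence))
    peptides = []
    for a in range(len(cuts) - 1):
        for b in range(a + 1, min(a + 2 + max_missed, len(cuts))):
            s, e = cuts[a], cuts[b]
            if e - s >= min_length:
                peptides.append((s, e))
    return peptides


def simulate_tags(records: Sequence[ProteinRecord], truth: GroundTruth,
                  config: SyntheticConfig) -> pd.DataFrame:
    """Emit the per-spectrum tag observation table and fill in the truth.

    Each spectrum draws an organism by its abundance fraction, a protein
    uniformly within it, a fully tryptic peptide uniformly, and a tag window
    uniformly within the peptide; the emitted rank-1 tag carries exact flank
    residue-sum masses (fixed carbamidomethyl C applied) plus Gaussian noise.
    With probability ``decoy_tag_fraction`` the rank-1 tag is instead a
    random decoy; remaining per-spectrum slots are always decoys.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    by_acc = {rec.accession: rec for rec in records}
    organisms = sorted(truth.organism_fractions)
    probs = np.array([truth.organism_fractions[o] for o in organisms])
    peptide_cache: Dict[str, List[Tuple[int, int]]] = {}
    k = config.tag_length

    rows: List[Tuple[str, str, str, str, str, int]] = []

    def decoy_row(key: SpectrumKey, rank: int) -> None:
        idx = rng.integers(0, len(_AA20), size=k)
        seq = "".join(_AA20[idx])
        n_gap, c_gap = rng.uniform(0.0, config.decoy_gap_max, size=2)
        rows.append((key.sample, key.spectrum_id, repr(float(n_gap)), seq,
                     repr(float(c_gap)), rank))

    for i in range(config.n_spectra):
        key = SpectrumKey(sample=f"s{1 + i % config.n_samples}",
                          spectrum_id=f"scan{i:06d}")
        is_decoy = rng.random() < config.decoy_tag_fraction
        if is_decoy:
            truth.decoy_spectra.add(key)
            decoy_row(key, 1)
        else:
            org = organisms[int(rng.choice(len(organisms), p=probs))]
            accs = truth.proteins_by_organism[org]
            acc = accs[int(rng.integers(0, len(accs)))]
            seq = by_acc[acc].sequence
            peps = peptide_cache.get(acc)
            if peps is None:
                peps = tryptic_peptides(seq, config.max_missed_cleavages,
                                        min_length=k)
                peptide_cache[acc] = peps
            s, e = peps[int(rng.integers(0, len(peps)))]
            peptide = seq[s:e]
            w = int(rng.integers(0, len(peptide) - k + 1))
            n_gap = flank_mass(peptide[:w], _FIXED)
            c_gap = flank_mass(peptide[w + k:], _FIXED)
            assert n_gap is not None and c_gap is not None
            if config.gap_noise_sd > 0:
                n_gap = max(0.0, n_gap + rng.normal(0.0, config.gap_noise_sd))
                c_gap = max(0.0, c_gap + rng.normal(0.0, config.gap_noise_sd))
            rows.append((key.sample, key.spectrum_id, repr(float(n_gap)),
                         peptide[w:w + k], repr(float(c_gap)), 1))
            truth.sources[key] = (acc, peptide, w)
            truth.sampled_accessions.add(acc)
        for rank in range(2, config.tags_per_spectrum + 1):
            decoy_row(key, rank)

    return pd.DataFrame(rows, columns=REQUIRED_COLUMNS)


def evaluate_recovery(retained_accessions: Sequence[str],
                      truth: GroundTruth,
                      records: Sequence[ProteinRecord],
                      organism_profile: Dict[str, float],
                      counts: SpectralCounts) -> Dict[str, float]:
    """Score a finished run against the ground truth.

    Metrics: protein recall (a retained isoform twin counts as a hit for its
    partner), protein precision, database size reduction factor, Spearman
    correlation between true organism fractions and the estimated organism
    profile, and coverage of the non-decoy spectra by the retained set.
    """
    retained = set(retained_accessions)
    sampled = set(truth.sampled_accessions)
    twin = truth.isoform_twin

    def hit(acc: str) -> bool:
        return acc in retained or twin.get(acc) in retained

    recall = (sum(1 for a in sampled if hit(a)) / len(sampled)) if sampled else 0.0
    precision = (
        sum(1 for a in retained if a in sampled or twin.get(a) in sampled)
        / len(retained)
    ) if retained else 0.0
    reduction = len(records) / len(retained) if retained else float("inf")

    orgs = sorted(truth.organism_fractions)
    true_vec = [truth.organism_fractions[o] for o in orgs]
    est_vec = [organism_profile.get(o, 0.0) for o in orgs]
    if len(orgs) > 1 and len(set(true_vec)) > 1 and len(set(est_vec)) > 1:
        spearman = float(stats.spearmanr(true_vec, est_vec).statistic)
    else:
        spearman = float("nan")

    true_spectra = set(truth.sources)
    covered = set()
    for acc in retained:
        for spectra in counts.get(acc, {}).values():
            covered |= spectra
    coverage = (len(true_spectra & covered) / len(true_spectra)
                if true_spectra else 0.0)

    return {
        "protein_recall": recall,
        "protein_precision": precision,
        "reduction_factor": reduction,
        "organism_spearman": spearman,
        "spectrum_coverage": coverage,
        "n_retained": float(len(retained)),
        "n_sampled_proteins": float(len(sampled)),
    }


def write_truth(truth: GroundTruth, dest) -> None:
    """Ground-truth manifest as a tab-separated table (one section per kind)."""
    rows = []
    for org, frac in sorted(truth.organism_fractions.items()):
        rows.append({"kind": "organism_fraction", "key": org, "value": repr(frac)})
    for acc in sorted(truth.sampled_accessions):
        rows.append({"kind": "sampled_accession", "key": acc, "value": ""})
    for key, (acc, peptide, w) in sorted(
            truth.sources.items(), key=lambda kv: (kv[0].sample, kv[0].spectrum_id)):
        rows.append({"kind": "spectrum_source",
                     "key": f"{key.sample}:{key.spectrum_id}",
                     "value": f"{acc}:{peptide}:{w}"})
    pd.DataFrame(rows, columns=["kind", "key", "value"]).to_csv(
        dest, sep="\t", index=False)
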