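"""Synthetic multi-locus sequence data with emergent substitution saturation.

Two simulation modes replace the study system's real sequence data:

* **mechanistic** -- finite-state nucleotide sequences evolved along the
  chronogram under a strict clock and a Kimura two-parameter substitution
  process.  Because the state space is finite, observed p-distances saturate
  naturally with depth: a fast mitochondrial locus is deep into saturation at
  waterbird-ordinal timescales while slow nuclear loci are only mildly bent.
* **stylized** -- pairwise distances drawn directly from a
  :class:`~satclock.saturation.SaturationModel` expectation, optionally with
  binomial sampling noise for a finite sequence length.  No sequences exist
  in this mode; it isolates the analytic saturation law from substitution-
  process detail.

The default locus panel mirrors a seven-locus nuclear set (five introns, one
exon, one 3'UTR; 1,000 bp each at the 1 %/MY pairwise background rate) plus
one concatenated mitochondrial partition (1,500 bp at 5x the nuclear rate).
Lengths and the mitochondrial rate multiplier are free parameters; the
defaults are chosen so that binomial noise does not mask the saturation bias
at desk scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .distances import DistanceMatrix
from .saturation import SaturationModel, expected_distance
from .trees import Chronogram

__all__ = [
    "LocusProfile",
    "Alignment",
    "simulate_alignment",
    "simulate_stylized_distances",
    "expected_p_distance",
    "DEFAULT_NUCLEAR_LOCI",
    "DEFAULT_MTDNA_LOCUS",
    "DEFAULT_LOCI",
    "BASE_PAIRWISE_RATE",
]

#: Pairwise percent distance accrued per MY between two diverging lineages
#: for a relative_rate of 1 (the nuclear background).
BASE_PAIRWISE_RATE = 1.0

_ALPHABET = "AGCT"  # order matters: transition partner = index XOR 1


@dataclass(frozen=True)
class LocusProfile:
    """A sequenced marker: its genome class, length and relative rate."""

    name: str
    genome_class: Literal["nDNA", "mtDNA"]
    length: int
    relative_rate: float
    kappa: float = 2.0  # transition/transversion rate ratio

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: length must be > 0")
        if self.relative_rate <= 0:
            raise ValueError(f"{self.name}: relative_rate must be > 0")
        if self.kappa <= 0:
            raise ValueError(f"{self.name}: kappa must be > 0")
        if self.genome_class not in ("nDNA", "mtDNA"):
            raise ValueError(f"{self.name}: genome_class must be nDNA or mtDNA")


DEFAULT_NUCLEAR_LOCI: tuple[LocusProfile, ...] = tuple(
    LocusProfile(name, "nDNA", 1000, 1.0)
    for name in (
        "NFKBIZ_intron6",
        "MB_intron2",
        "SLC29A4_intron8",
        "G3PDH_intron11",
        "TIMM17A_intron3",
        "ZENK_exon2",
        "ZENK_3UTR",
    )
)
DEFAULT_MTDNA_LOCUS = LocusProfile("mtDNA_CytbCOI", "mtDNA", 1500, 5.0, kappa=4.0)
DEFAULT_LOCI: tuple[LocusProfile, ...] = DEFAULT_NUCLEAR_LOCI + (DEFAULT_MTDNA_LOCUS,)


@dataclass
class Alignment:
    """Aligned sequences for one locus, encoded as integer states (A,G,C,T -> 0..3)."""

    locus: str
    labels: tuple
    data: np.ndarray  # shape (n_taxa, length), dtype int8

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.data = np.asarray(self.data, dtype=np.int8)
        if self.data.shape[0] != len(self.labels):
            raise ValueError("one row per taxon required")

    @property
    def length(self) -> int:
        return self.data.shape[1]

    def sequence(self, label: str) -> str:
        row = self.data[self.labels.index(label)]
        return "".join(_ALPHABET[s] for s in row)

    def subset(self, labels: Sequence[str]) -> "Alignment":
        idx = [self.labels.index(l) for l in labels]
        return Alignment(self.locus, tuple(labels), self.data[idx])

    def p_distance_matrix(self) -> DistanceMatrix:
        """Uncorrected pairwise p-distances in percent."""
        n = len(self.labels)
        d = np.zeros((n, n))
        for i in range(n):
            diff = (self.data[i + 1 :] != self.data[i]).mean(axis=1) * 100.0
            d[i, i + 1 :] = diff
            d[i + 1 :, i] = diff
        return DistanceMatrix(self.labels, d, self.locus)

    @classmethod
    def from_sequences(cls, locus: str, records: Sequence[tuple[str, str]]) -> "Alignment":
        labels = tuple(name for name, _ in records)
        lengths = {len(seq) for _, seq in records}
        if len(lengths) != 1:
            raise ValueError("sequences must be aligned (equal lengths)")
        lut = {c: i for i, c in enumerate(_ALPHABET)}
        data = np.array(
            [[lut[c] for c in seq.upper()] for _, seq in records], dtype=np.int8
        )
        return cls(locus, labels, data)


def _k2p_event_probs(d: float, kappa: float) -> tuple[float, float]:
    """(P[transition], P[each transversion]) after expected ``d`` subs/site."""
    beta = 1.0 / (kappa + 2.0)
    alpha = kappa * beta
    e1 = np.exp(-4.0 * beta * d)
    e2 = np.exp(-2.0 * (alpha + beta) * d)
    p_ts = 0.25 + 0.25 * e1 - 0.5 * e2
    p_tv_each = 0.25 * (1.0 - e1)  # total transversion prob is 0.5*(1-e1)
    return float(p_ts), float(p_tv_each)


def expected_p_distance(subs_per_site: float, kappa: float = 2.0) -> float:
    """Closed-form expected p-distance (proportion) under the K2P process."""
    p_ts, p_tv_each = _k2p_event_probs(subs_per_site, kappa)
    return p_ts + 2.0 * p_tv_each


def simulate_alignment(
    tree: Chronogram,
    locus: LocusProfile,
    mode: str = "mechanistic",
    seed: int = 0,
    base_rate: float = BASE_PAIRWISE_RATE,
) -> Alignment:
    """Evolve one locus along the chronogram under a strict clock.

    ``base_rate`` is the pairwise percent distance accrued per MY at
    relative_rate 1; per-lineage substitutions per site per MY are therefore
    ``base_rate * relative_rate / 200``.  A ``base_rate`` of exactly 0 yields
    identical sequences on all tips; negative rates are rejected.
    """
    if mode != "mechanistic":
        raise ValueError(
            "simulate_alignment only evolves sequences mechanistically; "
            "use simulate_stylized_distances for the stylized mode"
        )
    if base_rate < 0:
        raise ValueError("base_rate must be non-negative")
    if not tree.has_ages:
        raise ValueError("tree must carry branch lengths in MY")
    rng = np.random.default_rng(seed)
    mu = base_rate * locus.relative_rate / 200.0  # subs/site/MY per lineage
    L = locus.length
    root_seq = rng.integers(0, 4, size=L, dtype=np.int8)
    seqs: dict[str, np.ndarray] = {}

    def _evolve(parent_seq: np.ndarray, node) -> None:
        for child in node.child_nodes():
            d = mu * child.edge.length
            p_ts, p_tv_each = _k2p_event_probs(d, locus.kappa)
            u = rng.random(L)
            seq = parent_seq.copy()
            # event categories: [same | transition | transversion-1 | transversion-2]
            ts = u < p_ts
            tv1 = (u >= p_ts) & (u < p_ts + p_tv_each)
            tv2 = (u >= p_ts + p_tv_each) & (u < p_ts + 2 * p_tv_each)
            seq[ts] ^= 1
            seq[tv1] ^= 2
            seq[tv2] ^= 3
            if child.is_leaf():
                seqs[child.taxon.label] = seq
            else:
                _evolve(seq, child)

    _evolve(root_seq, tree.root)
    labels = tuple(tree.taxa)
    data = np.stack([seqs[l] for l in labels])
    return Alignment(locus.name, labels, data)


def simulate_stylized_distances(
    tree: Chronogram,
    model: SaturationModel | None = None,
    length: int | None = None,
    seed: int = 0,
) -> DistanceMatrix:
    """Pairwise distances drawn from a saturation-model expectation.

    Each pair's expected distance is the model evaluated at the age of the
    pair's MRCA.  With ``length`` given, binomial sampling noise for that
    many sites is added (one draw per pair, matrix kept symmetric); with
    ``length=None`` the exact expectations are returned.
    """
    if model is None:
        model = SaturationModel()
    if not tree.has_ages:
        raise ValueError("tree must carry node ages")
    rng = np.random.default_rng(seed)
    labels = tuple(tree.taxa)
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            age = tree.age_of([labels[i], labels[j]])
            exp_pct = expected_distance(model, age)
            if length is None:
                obs = exp_pct
            else:
                p = min(max(exp_pct / 100.0, 0.0), 1.0)
                obs = rng.binomial(length, p) / length * 100.0
            d[i, j] = d[j, i] = obs
    return DistanceMatrix(labels, d, locus="stylized")
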