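"""Codon-pair signature discovery for mRNA-selective translation reporters.

A translation reporter built from two fluorescently labeled tRNAs produces a
FRET signal whenever the two cognate codons are decoded at adjacent ribosomal
sites.  The signal is therefore mRNA-selective only if the consecutive
in-frame codon pair is rare across the transcriptome and the target mRNA
carries most of the ribosomal traffic over that pair.  This module builds an
inverted index from codon pairs to the transcripts that contain them and
scores candidate pairs by a signal-to-noise ratio (SNR):

    O_t(c)  = A_t * r_t * n_{t,c}        modeled ribosomal occupancy of
                                         transcript t at pair c
    SNR(c)  = O_target(c) / sum_{t != target} O_t(c)

where A_t is transcript abundance (e.g. TPM), r_t its relative ribosome
density, and n_{t,c} the number of in-frame occurrences of the pair.  A pair
unique to the target has no competing signal; its SNR is reported as the
``math.inf`` sentinel and ranks above every finite score.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

__all__ = [
    "CodonPair",
    "TranscriptRecord",
    "CodonPairIndex",
    "SignatureScore",
    "enumerate_codon_pairs",
    "build_pair_index",
    "signal_to_noise",
    "rank_signature_pairs",
    "codon_to_anticodon",
]

_VALID = set("ACGT")
_RNA_COMPLEMENT = {"A": "U", "C": "G", "G": "C", "T": "A"}


def _check_codon(codon: str) -> str:
    if len(codon) != 3 or not set(codon) <= _VALID:
        raise ValueError(f"invalid codon: {codon!r}")
    return codon


@dataclass(frozen=True, order=True)
class CodonPair:
    """An ordered pair of consecutive in-frame codons (DNA alphabet)."""

    first: str
    second: str

    def __post_init__(self) -> None:
        _check_codon(self.first)
        _check_codon(self.second)

    def __str__(self) -> str:  # e.g. "TCG|CAA"
        return f"{self.first}|{self.second}"

    @classmethod
    def from_string(cls, text: str) -> "CodonPair":
        parts = text.replace("-", "|").split("|")
        if len(parts) != 2:
            raise ValueError(f"cannot parse codon pair from {text!r}")
        return cls(parts[0].upper(), parts[1].upper())


@dataclass
class TranscriptRecord:
    """A coding sequence with expression metadata.

    abundance and ribo_density are relative units; only their product
    (scaled by occurrence count) enters the occupancy model.
    """

    transcript_id: str
    cds: str
    abundance: float = 1.0
    ribo_density: float = 1.0

    def __post_init__(self) -> None:
        self.cds = self.cds.upper()
        if len(self.cds) % 3 != 0:
            raise ValueError(
                f"{self.transcript_id}: CDS length {len(self.cds)} not divisible by 3"
            )
        if len(self.cds) < 6:
            raise ValueError(f"{self.transcript_id}: CDS shorter than two codons")
        if not set(self.cds) <= _VALID:
            raise ValueError(f"{self.transcript_id}: CDS contains non-ACGT characters")
        if self.abundance < 0 or self.ribo_density < 0:
            raise ValueError(f"{self.transcript_id}: negative abundance/density")

    @property
    def n_codons(self) -> int:
        return len(self.cds) // 3


def enumerate_codon_pairs(cds: str) -> list[tuple[int, CodonPair]]:
    """List all consecutive in-frame codon pairs of a CDS.

    Returns (codon_index, pair) tuples where codon_index is the 0-based
    index of the first codon of the pair; a CDS of L/3 codons yields
    L/3 - 1 pairs.  Overlapping occurrences of the same pair are listed
    separately.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not set(cds) <= _VALID:
        raise ValueError("CDS contains non-ACGT characters")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    return [
        (i, CodonPair(codons[i], codons[i + 1])) for i in range(len(codons) - 1)
    ]


@dataclass
class CodonPairIndex:
    """Inverted index pair -> [(transcript_id, occurrence count)]."""

    entries: dict[CodonPair, list[tuple[str, int]]] = field(default_factory=dict)
    transcript_count: int = 0

    def prevalence(self, pair: CodonPair) -> int:
        return len(self.entries.get(pair, []))

    def occurrences(self, pair: CodonPair) -> dict[str, int]:
        return dict(self.entries.get(pair, []))


def build_pair_index(transcripts: Sequence[TranscriptRecord]) -> CodonPairIndex:
    """Index every codon pair over a transcript set.

    Transcript-level counting with one record per gene expected; duplicate
    transcript ids are rejected.
    """
    seen: set[str] = set()
    entries: dict[CodonPair, list[tuple[str, int]]] = {}
    for rec in transcripts:
        if rec.transcript_id in seen:
            raise ValueError(f"duplicate transcript_id: {rec.transcript_id}")
        seen.add(rec.transcript_id)
        counts = Counter(pair for _, pair in enumerate_codon_pairs(rec.cds))
        for pair, n in counts.items():
            entries.setdefault(pair, []).append((rec.transcript_id, n))
    return CodonPairIndex(entries=entries, transcript_count=len(transcripts))


@dataclass
class SignatureScore:
    pair: CodonPair
    prevalence: int
    target_occupancy: float
    background_occupancy: float
    snr: float  # math.inf when the pair is unique to the target

    def sort_key(self) -> tuple:
        # inf first, then snr desc, ties by lower prevalence, then pair order
        return (-self.snr, self.prevalence, self.pair)


def _occupancy(
    rec: TranscriptRecord, n_occ: int, dwell: Mapping[CodonPair, float] | None, pair: CodonPair
) -> float:
    w = 1.0 if dwell is None else float(dwell.get(pair, 1.0))
    return rec.abundance * rec.ribo_density * n_occ * w


def signal_to_noise(
    index: CodonPairIndex,
    transcripts: Sequence[TranscriptRecord],
    target_id: str,
    pair: CodonPair,
    denominator: str = "sum",
    dwell: Mapping[CodonPair, float] | None = None,
) -> SignatureScore:
    """Score one codon pair as target occupancy over competing occupancy.

    denominator="sum" divides by the total occupancy of all other
    pair-containing transcripts (target vs total competing signal);
    "mean" divides by their mean instead.  Optional per-pair dwell-time
    weights multiply every occupancy uniformly and thus cancel in the
    ratio; they matter only when comparing pairs.
    """
    by_tid = {t.transcript_id: t for t in transcripts}
    if target_id not in by_tid:
        raise KeyError(f"unknown target transcript: {target_id}")
    occ = index.occurrences(pair)
    if target_id not in occ:
        raise ValueError(f"target {target_id} does not contain pair {pair}")
    target_o = _occupancy(by_tid[target_id], occ[target_id], dwell, pair)
    background = [
        _occupancy(by_tid[tid], n, dwell, pair) for tid, n in occ.items() if tid != target_id
    ]
    bg_total = sum(background)
    if denominator == "mean" and background:
        bg = bg_total / len(background)
    else:
        bg = bg_total
    snr = math.inf if bg == 0 else target_o / bg
    return SignatureScore(
        pair=pair,
        prevalence=len(occ),
        target_occupancy=target_o,
        background_occupancy=bg_total,
        snr=snr,
    )


def rank_signature_pairs(
    transcripts: Sequence[TranscriptRecord],
    target_id: str,
    top_k: int = 10,
    denominator: str = "sum",
    dwell: Mapping[CodonPair, float] | None = None,
    index: CodonPairIndex | None = None,
) -> list[SignatureScore]:
    """Rank the target's distinct codon pairs by SNR (descending).

    Ties break toward lower transcriptome prevalence, then lexicographic
    pair order.  Unique-to-target pairs (infinite SNR) rank first.
    """
    if top_k < 1:
        raise ValueError("top_k must be >= 1")
    by_tid = {t.transcript_id: t for t in transcripts}
    if target_id not in by_tid:
        raise KeyError(f"unknown target transcript: {target_id}")
    if index is None:
        index = build_pair_index(transcripts)
    target_pairs = sorted({p for _, p in enumerate_codon_pairs(by_tid[target_id].cds)})
    scores = [
        signal_to_noise(index, transcripts, target_id, p, denominator, dwell)
        for p in target_pairs
    ]
    scores.sort(key=SignatureScore.sort_key)
    return scores[:top_k]


def codon_to_anticodon(codon: str) -> str:
    """Anticodon of a codon: reverse complement, RNA alphabet, written 5'->3'.

    E.g. CAA -> UUG (Gln tRNA).  T and U are accepted on input.
    """
    codon = codon.upper().replace("U", "T")
    _check_codon(codon)
    return "".join(_RNA_COMPLEMENT[b] for b in reversed(codon))
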