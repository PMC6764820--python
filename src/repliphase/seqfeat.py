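"""IDR sequence analytics.

Operations for characterizing intrinsically disordered regions of
replication initiation factors: longest-disordered-run extraction from
per-residue disorder scores, amino-acid class composition, isoelectric
point, fraction of charged residues (FCR), Wootton–Federhen sliding-
window compositional complexity, CDK phosphorylation consensus
scanning, and oligo GC utilities.

Sequence coordinates are 1-based inclusive throughout this module
(image coordinates elsewhere in the package are 0-based).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioRecord

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"

#: Amino-acid classes used for IDR composition profiling.
AA_CLASSES = {
    "aromatic": set("FWY"),
    "hydrophobic": set("AGILMPV"),
    "hydrophilic": set("CNQST"),
    "charged": set("DEHKR"),
}
POSITIVE = set("KR")
NEGATIVE = set("DE")
FCR_RESIDUES = set("DEKR")  # H is in the charged class but excluded from FCR

#: Bjellqvist-style pKa table (swappable; see docs/methods.md).
DEFAULT_PKA = {
    "n_term": 7.50,
    "c_term": 3.55,
    "D": 4.05, "E": 4.45, "C": 9.00, "Y": 10.00,
    "H": 5.98, "K": 10.00, "R": 12.00,
}


@dataclass(frozen=True)
class Interval:
    """1-based inclusive residue interval."""

    start: int
    end: int

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ValueError(f"invalid interval ({self.start}, {self.end})")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


@dataclass
class SequenceRecord:
    """A validated one-letter sequence with its molecule type."""

    id: str
    residues: str
    molecule: str = "protein"  # "protein" | "dna"

    def __post_init__(self):
        if self.molecule not in ("protein", "dna"):
            raise ValueError("molecule must be 'protein' or 'dna'")
        alphabet = PROTEIN_ALPHABET if self.molecule == "protein" else DNA_ALPHABET
        self.residues = self.residues.upper()
        bad = set(self.residues) - set(alphabet)
        if bad:
            raise ValueError(f"invalid {self.molecule} characters: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    def subsequence(self, interval: Interval | None) -> str:
        if interval is None:
            return self.residues
        if interval.end > len(self):
            raise ValueError("interval extends past the sequence end")
        return self.residues[interval.start - 1:interval.end]


@dataclass
class DisorderProfile:
    """Per-residue disorder scores in [0, 1], aligned 1:1 with a sequence."""

    scores: np.ndarray

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=np.float64)
        if self.scores.ndim != 1:
            raise ValueError("scores must be one-dimensional")
        if self.scores.size and (self.scores.min() < 0 or self.scores.max() > 1):
            raise ValueError("disorder scores must lie in [0, 1]")

    def __len__(self) -> int:
        return len(self.scores)


# -- FASTA / TSV IO ---------------------------------------------------------

def read_fasta(path, molecule: str = "protein") -> list[SequenceRecord]:
    return [SequenceRecord(id=r.id, residues=str(r.seq), molecule=molecule)
            for r in SeqIO.parse(str(path), "fasta")]


def write_fasta(records: list[SequenceRecord], path) -> None:
    SeqIO.write([_BioRecord(Seq(r.residues), id=r.id, description="")
                 for r in records], str(path), "fasta")


def read_disorder_tsv(path) -> DisorderProfile:
    """Read a (position, score) TSV; positions must be 1..L in order."""
    df = pd.read_csv(path, sep="\t")
    df = df.sort_values(df.columns[0])
    positions = df.iloc[:, 0].to_numpy()
    if not np.array_equal(positions, np.arange(1, len(df) + 1)):
        raise ValueError("disorder TSV positions must be contiguous from 1")
    return DisorderProfile(scores=df.iloc[:, 1].to_numpy())


# -- IDR extraction ---------------------------------------------------------

def idr_from_scores(profile: DisorderProfile, cutoff: float = 0.5) -> Interval | None:
    """Longest contiguous run of residues with score > cutoff.

    Ties break to the earliest run; ``None`` if no residue is above the
    cutoff.
    """
    if len(profile) == 0:
        raise ValueError("empty disorder profile")
    above = profile.scores > cutoff
    best = None
    start = None
    for i, flag in enumerate(np.append(above, False)):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            length = i - start
            if best is None or length > (best.end - best.start + 1):
                best = Interval(start + 1, i)
            start = None
    return best


# -- composition ------------------------------------------------------------

@dataclass
class CompositionProfile:
    """Class fractions, charge fractions, FCR, pI and length of a region."""

    length: int
    class_fractions: dict[str, float]
    positive_fraction: float
    negative_fraction: float
    fcr: float
    pi: float


def class_composition(seq: SequenceRecord, interval: Interval | None = None) -> dict[str, float]:
    """Fractions of the four amino-acid classes over a region (sums to 1)."""
    if seq.molecule != "protein":
        raise ValueError("class composition is defined for protein sequences")
    sub = seq.subsequence(interval)
    if not sub:
        raise ValueError("empty region")
    n = len(sub)
    return {name: sum(sub.count(a) for a in members) / n
            for name, members in AA_CLASSES.items()}


def fraction_charged(seq: SequenceRecord, interval: Interval | None = None) -> float:
    """FCR = (nD + nE + nK + nR) / L (histidine excluded)."""
    sub = seq.subsequence(interval)
    if not sub:
        raise ValueError("empty region")
    return sum(sub.count(a) for a in FCR_RESIDUES) / len(sub)


def net_charge(sub: str, ph: float, pka: dict[str, float] = DEFAULT_PKA) -> float:
    """Modeled net charge at a given pH (Henderson–Hasselbalch terms over
    D, E, C, Y, H, K, R and the two termini)."""
    pos = ("H", "K", "R")
    neg = ("D", "E", "C", "Y")
    q = 1.0 / (1.0 + 10 ** (ph - pka["n_term"]))
    q -= 1.0 / (1.0 + 10 ** (pka["c_term"] - ph))
    for a in pos:
        q += sub.count(a) / (1.0 + 10 ** (ph - pka[a]))
    for a in neg:
        q -= sub.count(a) / (1.0 + 10 ** (pka[a] - ph))
    return q


def isoelectric_point(seq: SequenceRecord, interval: Interval | None = None,
                      pka: dict[str, float] = DEFAULT_PKA,
                      tol: float = 1e-4) -> float:
    """pH at which the modeled net charge crosses zero (bisection)."""
    if seq.molecule != "protein":
        raise ValueError("pI is defined for protein sequences")
    sub = seq.subsequence(interval)
    if not sub:
        raise ValueError("empty region")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-9:
        mid = (lo + hi) / 2
        q = net_charge(sub, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def composition_profile(seq: SequenceRecord, interval: Interval | None = None) -> CompositionProfile:
    sub = seq.subsequence(interval)
    n = len(sub)
    return CompositionProfile(
        length=n,
        class_fractions=class_composition(seq, interval),
        positive_fraction=sum(sub.count(a) for a in POSITIVE) / n,
        negative_fraction=sum(sub.count(a) for a in NEGATIVE) / n,
        fcr=fraction_charged(seq, interval),
        pi=isoelectric_point(seq, interval),
    )


# -- compositional complexity ----------------------------------------------

@dataclass
class ComplexityProfile:
    """Per-residue Wootton–Federhen complexity (NaN where the sliding
    window does not fit), window length, and alphabet size."""

    scores: np.ndarray
    window: int
    n_symbols: int = 20

    def summary_by_disorder(self, profile: DisorderProfile,
                            cutoff: float = 0.5) -> dict[str, float]:
        """Mean complexity over predicted disordered vs ordered residues."""
        if len(profile) != len(self.scores):
            raise ValueError("disorder profile length mismatch")
        scored = ~np.isnan(self.scores)
        disordered = (profile.scores > cutoff) & scored
        ordered = (profile.scores <= cutoff) & scored
        return {
            "disordered_mean": float(np.mean(self.scores[disordered])) if disordered.any() else float("nan"),
            "ordered_mean": float(np.mean(self.scores[ordered])) if ordered.any() else float("nan"),
        }


def window_complexity(window_seq: str, n_symbols: int = 20) -> float:
    """K = ln(L! / Π n_i!) / (L · ln N): 0 for a homopolymer, < 1 always."""
    L = len(window_seq)
    counts = {}
    for ch in window_seq:
        counts[ch] = counts.get(ch, 0) + 1
    log_multinomial = math.lgamma(L + 1) - sum(math.lgamma(c + 1) for c in counts.values())
    return log_multinomial / (L * math.log(n_symbols))


def local_complexity(seq: SequenceRecord, window: int = 20,
                     n_symbols: int = 20) -> ComplexityProfile:
    """Sliding-window complexity assigned to each window's central residue;
    residues whose window does not fit carry no score (NaN)."""
    if seq.molecule != "protein":
        raise ValueError("complexity is defined for protein sequences")
    L = len(seq)
    if L < window:
        raise ValueError(f"sequence length {L} shorter than window {window}")
    scores = np.full(L, np.nan)
    for start in range(L - window + 1):
        scores[start + window // 2] = window_complexity(
            seq.residues[start:start + window], n_symbols)
    return ComplexityProfile(scores=scores, window=window, n_symbols=n_symbols)


# -- CDK consensus scanning --------------------------------------------------

@dataclass
class MotifHits:
    """CDK consensus matches: minimal = [S/T]P; full = [S/T]PX[K/R].

    Positions are 1-based at the S/T residue; full hits are a subset of
    minimal hits; overlapping occurrences are all reported.
    """

    minimal: list[int]
    full: list[int]

    @property
    def n_minimal(self) -> int:
        return len(self.minimal)

    @property
    def n_full(self) -> int:
        return len(self.full)

    def restrict(self, interval: Interval) -> "MotifHits":
        return MotifHits(minimal=[p for p in self.minimal if interval.contains(p)],
                         full=[p for p in self.full if interval.contains(p)])


def cdk_site_scan(seq: SequenceRecord, interval: Interval | None = None) -> MotifHits:
    """Scan a protein sequence for CDK phosphorylation consensus motifs."""
    if seq.molecule != "protein":
        raise ValueError("CDK scan is defined for protein sequences")
    s = seq.residues
    minimal, full = [], []
    for i in range(len(s) - 1):
        if s[i] in "ST" and s[i + 1] == "P":
            minimal.append(i + 1)
            if i + 3 < len(s) and s[i + 3] in "KR":
                full.append(i + 1)
    hits = MotifHits(minimal=minimal, full=full)
    return hits.restrict(interval) if interval is not None else hits


# -- DNA utilities ------------------------------------------------------------

def gc_content(seq: SequenceRecord) -> float:
    """(nG + nC) / L of a DNA sequence."""
    if seq.molecule != "dna":
        raise ValueError("GC content is defined for DNA sequences")
    if len(seq) == 0:
        raise ValueError("empty sequence")
    s = seq.residues
    return (s.count("G") + s.count("C")) / len(s)


def reverse_complement(seq: SequenceRecord) -> SequenceRecord:
    comp = str.maketrans("ACGT", "TGCA")
    return SequenceRecord(id=seq.id + "_rc",
                          residues=seq.residues.translate(comp)[::-1],
                          molecule="dna")


# -- feature tables -----------------------------------------------------------

def feature_table(records: list[SequenceRecord],
                  disorder: dict[str, DisorderProfile] | None = None,
                  intervals: dict[str, Interval] | None = None,
                  cutoff: float = 0.5) -> pd.DataFrame:
    """One row per record: id, IDR interval, IDR length, pI, FCR.

    Each record needs either an explicit interval (used verbatim) or a
    disorder profile (longest run above the cutoff). A record with no
    disordered run yields null interval fields.
    """
    disorder = disorder or {}
    intervals = intervals or {}
    rows = []
    for rec in records:
        if rec.id in intervals:
            iv = intervals[rec.id]
        elif rec.id in disorder:
            iv = idr_from_scores(disorder[rec.id], cutoff=cutoff)
        else:
            raise ValueError(f"record {rec.id}: no disorder profile or interval")
        if iv is None:
            rows.append({"id": rec.id, "idr_start": None, "idr_end": None,
                         "idr_length": None, "pI": None, "FCR": None})
        else:
            rows.append({
                "id": rec.id,
                "idr_start": iv.start,
                "idr_end": iv.end,
                "idr_length": len(iv),
                "pI": round(isoelectric_point(rec, iv), 2),
                "FCR": round(fraction_charged(rec, iv), 3),
            })
    return pd.DataFrame(rows)


def load_sequence_dir(directory, molecule: str = "protein") -> dict[str, SequenceRecord]:
    """Read every ``*.fasta``/``*.fa`` file in a directory into a dict by id."""
    out: dict[str, SequenceRecord] = {}
    for path in sorted(Path(directory).glob("*.fa*")):
        for rec in read_fasta(path, molecule=molecule):
            out[rec.id] = rec
    return out
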