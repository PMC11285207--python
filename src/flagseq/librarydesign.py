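"""Antigen-library encoding: peptide tiling, reverse translation with
restriction-site avoidance, and Hamming-distance error-correcting barcodes.

Tiling splits proteins into overlapping peptides (default 64 aa with a 20 aa
overlap); the final tile is anchored to the protein's last residue so the
C-terminus is always covered.  Reverse translation uses a bundled codon-usage
table biased toward highly expressed *E. coli* genes and excludes restriction
sites from the coding sequence.  Barcode codes are built by seeded greedy
rejection sampling and decoded by bounded-distance nearest-codeword search.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np

from .errors import CapacityError, EncodingError, ParameterError

STANDARD_AA = "ACDEFGHIKLMNPQRSTVWY"
NUCLEOTIDES = "ACGT"

# Recognition sequences of the cloning enzymes (standard enzyme constants).
ECORI_SITE = "GAATTC"
HINDIII_SITE = "AAGCTT"
SWAI_SITE = "ATTTAAAT"
DEFAULT_FORBIDDEN = (ECORI_SITE, HINDIII_SITE)

#: Standard genetic code, used to verify round trips internally.
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}


@dataclass(frozen=True)
class TilingParams:
    """Peptide tiling geometry: maximum tile length and inter-tile overlap."""

    max_len: int = 64
    overlap: int = 20

    def __post_init__(self):
        if not (0 < self.overlap < self.max_len):
            raise ParameterError(
                f"require 0 < overlap < max_len, got overlap={self.overlap}, "
                f"max_len={self.max_len}"
            )


@dataclass(frozen=True)
class PeptideTile:
    """A library peptide: parent protein id, 1-based inclusive span, sequence."""

    peptide_id: str
    parent_id: str
    start: int
    end: int
    sequence: str

    def __post_init__(self):
        if not (1 <= self.start <= self.end):
            raise ParameterError(f"bad tile span {self.start}-{self.end}")
        if len(self.sequence) != self.end - self.start + 1:
            raise ParameterError("tile sequence length does not match its span")


def tile_protein(sequence, params=TilingParams(), parent_id="protein",
                 id_prefix=None):
    """Split ``sequence`` into overlapping tiles.

    Consecutive tile starts advance by ``max_len - overlap``; the final tile is
    end-anchored at the last residue (its overlap with the previous tile may
    therefore exceed ``overlap``).  Returns a list of :class:`PeptideTile` with
    1-based inclusive coordinates covering every residue.
    """
    if not sequence:
        raise ParameterError("cannot tile an empty sequence")
    L = len(sequence)
    spans = []
    if L <= params.max_len:
        spans.append((1, L))
    else:
        step = params.max_len - params.overlap
        s = 1
        while True:
            e = s + params.max_len - 1
            if e >= L:
                spans.append((L - params.max_len + 1, L))
                break
            spans.append((s, e))
            s += step
    prefix = id_prefix if id_prefix is not None else parent_id
    return [
        PeptideTile(f"{prefix}_{s}_{e}", parent_id, s, e, sequence[s - 1:e])
        for s, e in spans
    ]


@dataclass(frozen=True)
class CodonTable:
    """Residue -> ranked codons with usage weights (stop codons under '*')."""

    codons: dict = field(default_factory=dict)

    def __post_init__(self):
        for residue in STANDARD_AA + "*":
            ranked = self.codons.get(residue)
            if not ranked:
                raise ParameterError(f"no codons for residue {residue!r}")
            for codon, _w in ranked:
                if len(codon) != 3 or set(codon) - set(NUCLEOTIDES):
                    raise ParameterError(f"invalid codon {codon!r}")
                if GENETIC_CODE[codon] != residue:
                    raise ParameterError(
                        f"codon {codon} does not encode {residue!r}")

    def ranked(self, residue):
        return [c for c, _ in self.codons[residue]]


def load_codon_table(path=None):
    """Load a ``residue<TAB>codon<TAB>weight`` TSV; defaults to the bundled
    high-expression *E. coli* table."""
    if path is None:
        ref = importlib.resources.files("flagseq.data") / "ecoli_codon_usage.tsv"
        text = ref.read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    codons = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, codon, weight = line.split("\t")
        codons.setdefault(residue, []).append((codon, float(weight)))
    for residue in codons:
        codons[residue].sort(key=lambda cw: -cw[1])
    return CodonTable(codons)


def translate(dna):
    """Translate a coding DNA string with the standard genetic code."""
    if len(dna) % 3:
        raise ParameterError("coding sequence length must be a multiple of 3")
    return "".join(GENETIC_CODE[dna[i:i + 3]] for i in range(0, len(dna), 3))


def _variant_choices(peptide, table, variant_index):
    """Mixed-radix decomposition of ``variant_index`` over the degenerate
    positions, yielding one codon-rank choice per residue."""
    radices = [len(table.codons[aa]) for aa in peptide]
    capacity = 1
    for r in radices:
        capacity *= r
    if variant_index < 0 or (variant_index > 0 and variant_index >= capacity):
        raise ParameterError(
            f"variant_index {variant_index} exceeds the {capacity} distinct "
            f"encodings of this peptide")
    choices = []
    v = variant_index
    for r in radices:
        choices.append(v % r)
        v //= r
    return choices


def reverse_translate(peptide, table=None, forbidden=DEFAULT_FORBIDDEN,
                      variant_index=0):
    """Reverse translate ``peptide`` into DNA avoiding ``forbidden`` motifs.

    ``variant_index`` selects an alternate codon assignment of the same
    peptide (distinct DNA for distinct indices), used to discriminate
    identical peptide sequences.  Raises :class:`EncodingError` naming the
    offending position when no codon substitution can remove a forbidden
    motif.
    """
    if table is None:
        table = _default_table()
    peptide = peptide.upper()
    bad = set(peptide) - set(STANDARD_AA)
    if not peptide or bad:
        raise ParameterError(f"non-standard residues in peptide: {sorted(bad)}")
    if any(not m for m in forbidden):
        raise ParameterError("forbidden motifs must be non-empty strings")

    choices = _variant_choices(peptide, table, variant_index)
    codons = [table.ranked(aa)[c] for aa, c in zip(peptide, choices)]

    def scan(codon_list):
        dna = "".join(codon_list)
        hits = []
        for motif in forbidden:
            p = dna.find(motif)
            while p != -1:
                hits.append((p, motif))
                p = dna.find(motif, p + 1)
        return dna, sorted(hits)

    for _ in range(10 * len(peptide) + 10):
        dna, hits = scan(codons)
        if not hits:
            return dna
        pos, motif = hits[0]
        first = pos // 3
        last = (pos + len(motif) - 1) // 3
        fixed = False
        for idx in range(first, last + 1):
            current = codons[idx]
            for alt in table.ranked(peptide[idx]):
                if alt == current:
                    continue
                trial = list(codons)
                trial[idx] = alt
                _, trial_hits = scan(trial)
                if len(trial_hits) < len(hits):
                    codons = trial
                    fixed = True
                    break
            if fixed:
                break
        if not fixed:
            raise EncodingError(
                f"cannot remove forbidden motif {motif} at nt position {pos}",
                position=pos)
    raise EncodingError("forbidden-motif elimination did not converge")


_TABLE_CACHE = None


def _default_table():
    global _TABLE_CACHE
    if _TABLE_CACHE is None:
        _TABLE_CACHE = load_codon_table()
    return _TABLE_CACHE


@dataclass(frozen=True)
class EncodedOligo:
    peptide_id: str
    dna: str
    oligo_length: int
    forbidden_sites_absent: bool


def encode_oligo(tile, oligo_length=230, table=None,
                 forbidden=DEFAULT_FORBIDDEN, variant_index=0, seed=0):
    """Encode a peptide tile as a fixed-length oligo: coding sequence + stop
    codon, padded with seeded random nucleotides to ``oligo_length`` (short
    peptides additionally receive a SwaI failsafe site in the padding)."""
    if table is None:
        table = _default_table()
    coding = reverse_translate(tile.sequence, table, forbidden, variant_index)
    stop = table.ranked("*")[0]
    body = coding + stop
    if len(body) > oligo_length:
        raise ParameterError(
            f"peptide {tile.peptide_id} needs {len(body)} nt > oligo length "
            f"{oligo_length}")
    pad_len = oligo_length - len(body)
    pad = ""
    if pad_len:
        if pad_len >= len(SWAI_SITE):
            pad_len -= len(SWAI_SITE)
            pad = SWAI_SITE
        rng = np.random.default_rng(seed)
        pad += "".join(rng.choice(list(NUCLEOTIDES), pad_len))
    dna = body + pad
    absent = all(m not in coding for m in forbidden)
    return EncodedOligo(tile.peptide_id, dna, oligo_length, absent)


# ---------------------------------------------------------------------------
# Error-correcting barcodes
# ---------------------------------------------------------------------------

_NT_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}


def _to_array(words):
    return np.array([[_NT_INDEX[c] for c in w] for w in words], dtype=np.uint8)


@dataclass(frozen=True)
class BarcodeCode:
    """A set of equal-length DNA codewords with guaranteed minimum pairwise
    Hamming distance."""

    codeword_length: int
    min_distance: int
    codewords: tuple

    @property
    def correctable_errors(self):
        """Substitution errors correctable by bounded-distance decoding."""
        return (self.min_distance - 1) // 2

    def __post_init__(self):
        if any(len(w) != self.codeword_length for w in self.codewords):
            raise ParameterError("codewords must all have codeword_length")


def build_barcode_code(length, min_distance, n_codewords, seed=0,
                       max_attempts=None):
    """Greedy rejection sampling of ``n_codewords`` random codewords, each
    accepted only if at Hamming distance >= ``min_distance`` from every
    previously accepted one.  Deterministic per seed; raises
    :class:`CapacityError` when the attempt budget is exhausted."""
    if min_distance < 1 or n_codewords < 1 or length < 1:
        raise ParameterError("length, min_distance and n_codewords must be >= 1")
    if min_distance > length:
        raise CapacityError(
            f"min_distance {min_distance} exceeds codeword length {length}")
    if max_attempts is None:
        max_attempts = max(10_000, 200 * n_codewords)
    rng = np.random.default_rng(seed)
    accepted = np.empty((0, length), dtype=np.uint8)
    words = []
    attempts = 0
    while len(words) < n_codewords:
        if attempts >= max_attempts:
            raise CapacityError(
                f"placed only {len(words)}/{n_codewords} codewords within "
                f"{max_attempts} attempts")
        attempts += 1
        cand = rng.integers(0, 4, size=length, dtype=np.uint8)
        if accepted.size and int((accepted != cand).sum(axis=1).min()) < min_distance:
            continue
        accepted = np.vstack([accepted, cand])
        words.append("".join(NUCLEOTIDES[i] for i in cand))
    return BarcodeCode(length, min_distance, tuple(words))


def decode_barcode(read, code):
    """Bounded-distance decode: return the unique codeword within
    ``(min_distance - 1) // 2`` substitutions of ``read``, or ``None``
    (rejection).  Ambiguous reads are always rejected."""
    if len(read) != code.codeword_length:
        raise ParameterError(
            f"read length {len(read)} != codeword length {code.codeword_length}")
    if set(read) - set(NUCLEOTIDES):
        raise ParameterError("read contains non-ACGT characters")
    arr = _to_array(code.codewords)
    r = _to_array([read])[0]
    dists = (arr != r).sum(axis=1)
    best = int(dists.min())
    if best > code.correctable_errors:
        return None
    if int((dists == best).sum()) > 1:
        return None
    return code.codewords[int(dists.argmin())]
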