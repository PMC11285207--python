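"""Pairwise protein alignment, percent identity, N-/C-terminal domain
annotation against reference domains, and relative epitope-position
profiling.

Alignment uses BLOSUM62 with affine gaps (open 11, extend 1): a gap run of
length L costs 11 + (L - 1).  Identity is computed over all aligned columns
(matches + mismatches + gaps).  Domain annotation places the footprint of
the best-scoring local alignment against a set of reference domains, with
structural priors: the N-terminal domain must start in the first half of
the protein and the C-terminal domain must end in its last quarter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .errors import ParameterError

VALID_AA = set("ACDEFGHIKLMNPQRSTVWY")

GAP_OPEN = 11
GAP_EXTEND = 1


@lru_cache(maxsize=8)
def _aligner(mode, gap_open=GAP_OPEN, gap_extend=GAP_EXTEND):
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = mode
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    return aligner


@dataclass(frozen=True)
class AlignmentResult:
    query_id: str
    target_id: str
    mode: str
    score: float
    aligned_length: int
    identities: int
    identity_pct: float
    query_span: tuple
    target_span: tuple


def _check_sequence(seq, name):
    bad = set(seq) - VALID_AA
    if not seq or bad:
        raise ParameterError(
            f"{name} is empty or contains non-amino-acid characters: "
            f"{sorted(bad)}")


def align(query, target, mode="global", query_id="query", target_id="target",
          gap_open=GAP_OPEN, gap_extend=GAP_EXTEND):
    """Optimal pairwise alignment; returns an :class:`AlignmentResult` or
    ``None`` for a local alignment with no positive-scoring region."""
    if mode not in ("global", "local"):
        raise ParameterError(f"mode must be global or local, got {mode!r}")
    _check_sequence(query, "query")
    _check_sequence(target, "target")
    aligner = _aligner(mode, gap_open, gap_extend)
    alignments = aligner.align(query, target)
    try:
        best = alignments[0]
    except IndexError:
        return None
    counts = best.counts()
    aligned_length = counts.identities + counts.mismatches + counts.gaps
    if aligned_length == 0:
        return None
    q_idx, t_idx = best.aligned[0], best.aligned[1]
    if len(q_idx) == 0:
        return None
    query_span = (int(q_idx[0][0]) + 1, int(q_idx[-1][1]))
    target_span = (int(t_idx[0][0]) + 1, int(t_idx[-1][1]))
    return AlignmentResult(
        query_id=query_id, target_id=target_id, mode=mode,
        score=float(best.score), aligned_length=int(aligned_length),
        identities=int(counts.identities),
        identity_pct=100.0 * counts.identities / aligned_length,
        query_span=query_span, target_span=target_span)


def identity_pct(query, target, mode="global"):
    """Convenience wrapper returning just the percent identity."""
    result = align(query, target, mode=mode)
    return result.identity_pct if result is not None else 0.0


# ---------------------------------------------------------------------------
# Domain annotation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DomainAnnotation:
    protein_id: str
    protein_length: int
    n_domain: tuple | None
    c_domain: tuple | None
    n_source_ref: str | None = None
    c_source_ref: str | None = None

    def _rel(self, value):
        return value / self.protein_length

    @property
    def rel_n_start(self):
        return self._rel(self.n_domain[0]) if self.n_domain else None

    @property
    def rel_n_end(self):
        return self._rel(self.n_domain[1]) if self.n_domain else None

    @property
    def rel_c_start(self):
        return self._rel(self.c_domain[0]) if self.c_domain else None

    @property
    def rel_c_end(self):
        return self._rel(self.c_domain[1]) if self.c_domain else None


def _best_footprint(protein, refs, min_score, constraint):
    """Best-scoring valid local-alignment footprint of any reference on the
    protein.  ``refs`` is a list of (ref_id, sequence); the reference order
    encodes the retry preference (default reference first)."""
    best = None
    best_ref = None
    for ref_id, ref_seq in refs:
        result = align(ref_seq, protein, mode="local", query_id=ref_id,
                       target_id="protein")
        if result is None or result.score < min_score:
            continue
        span = result.target_span
        if not constraint(span):
            continue
        if best is None or result.score > best.score:
            best = result
            best_ref = ref_id
    if best is None:
        return None, None
    return best.target_span, best_ref


def annotate_domains(protein, n_refs, c_refs, min_score=100.0,
                     protein_id="protein"):
    """Annotate N-/C-terminal domains by mapping reference domains onto the
    protein.  ``n_refs``/``c_refs`` are lists of (id, sequence) or plain
    sequences; absence of a domain is a legal result."""
    if not n_refs or not c_refs:
        raise ParameterError("reference lists must be non-empty")
    _check_sequence(protein, "protein")

    def normalize(refs, prefix):
        out = []
        for i, r in enumerate(refs):
            if isinstance(r, tuple):
                out.append(r)
            else:
                out.append((f"{prefix}{i}", r))
        return out

    L = len(protein)
    n_span, n_ref = _best_footprint(
        protein, normalize(n_refs, "nref"), min_score,
        lambda span: span[0] <= L / 2)
    c_span, c_ref = _best_footprint(
        protein, normalize(c_refs, "cref"), min_score,
        lambda span: span[1] >= 0.75 * L)
    if n_span and c_span and c_span[0] <= n_span[1]:
        # Overlapping footprints: keep the N domain, drop the C domain
        # unless it can be cleanly trimmed to start after the N domain.
        if c_span[1] > n_span[1] + 1:
            c_span = (n_span[1] + 1, c_span[1])
        else:
            c_span, c_ref = None, None
    return DomainAnnotation(protein_id, L, n_span, c_span, n_ref, c_ref)


def relative_start(start, parent_length):
    """Relative peptide position: 1-based start over parent protein length."""
    if not (1 <= start <= parent_length):
        raise ParameterError(
            f"start {start} outside protein of length {parent_length}")
    return start / parent_length


def domain_position_summary(annotations, boundary, bins):
    """Fraction of domain boundaries falling in each relative-position bin.

    ``boundary`` is one of ``n_start``, ``n_end``, ``c_start``, ``c_end``;
    ``bins`` is a list of (lo, hi) intervals over (0, 1], interpreted as
    lo < x <= hi.  Boundaries over a full partition of (0, 1] sum to 1.
    """
    attr = {"n_start": "rel_n_start", "n_end": "rel_n_end",
            "c_start": "rel_c_start", "c_end": "rel_c_end"}.get(boundary)
    if attr is None:
        raise ParameterError(f"unknown boundary {boundary!r}")
    values = [getattr(a, attr) for a in annotations
              if getattr(a, attr) is not None]
    if not values:
        raise ParameterError(f"no annotation carries boundary {boundary!r}")
    values = np.asarray(values)
    rows = []
    for lo, hi in bins:
        frac = float(np.mean((values > lo) & (values <= hi)))
        rows.append({"lo": lo, "hi": hi, "fraction": frac})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Prevalence ratios
# ---------------------------------------------------------------------------

def prevalence_ratio(seropositivity, groups):
    """Per-peptide seropositivity prevalence by group and the case/control
    prevalence ratio.

    ``seropositivity`` is a peptide x sample boolean DataFrame; ``groups``
    maps sample -> {case, control}.  A zero count in either group is replaced
    by half a subject (continuity correction) before forming the ratio.
    """
    groups = pd.Series(groups)
    unknown = set(groups.unique()) - {"case", "control"}
    if unknown:
        raise ParameterError(f"unknown group labels: {sorted(unknown)}")
    case_samples = groups.index[groups == "case"]
    ctrl_samples = groups.index[groups == "control"]
    if len(case_samples) == 0 or len(ctrl_samples) == 0:
        raise ParameterError("both groups must be non-empty")
    sero = seropositivity.astype(bool)
    n_case, n_ctrl = len(case_samples), len(ctrl_samples)
    case_counts = sero[case_samples].sum(axis=1).astype(float)
    ctrl_counts = sero[ctrl_samples].sum(axis=1).astype(float)
    prev_case = case_counts / n_case
    prev_ctrl = ctrl_counts / n_ctrl
    case_adj = case_counts.where(case_counts > 0, 0.5) / n_case
    ctrl_adj = ctrl_counts.where(ctrl_counts > 0, 0.5) / n_ctrl
    ratio = case_adj / ctrl_adj
    return pd.DataFrame({
        "prevalence_case": prev_case,
        "prevalence_control": prev_ctrl,
        "prevalence_ratio": ratio,
    })


def filter_prevalent(prevalence, min_prevalence=0.05, min_ratio=None):
    """Peptides with prevalence above threshold in either group, optionally
    also above a prevalence-ratio threshold (e.g. 2.5, 15, 20, 25)."""
    mask = ((prevalence["prevalence_case"] > min_prevalence)
            | (prevalence["prevalence_control"] > min_prevalence))
    if min_ratio is not None:
        mask &= prevalence["prevalence_ratio"] > min_ratio
    return prevalence[mask]
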