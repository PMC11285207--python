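"""Stimulator/silent/evader classification and class-similarity profiling
of antibody-bound flagellins.

Classes are defined relative to a PIM-like reference point: both readouts
stronger -> stimulator; both weaker -> evader; binding stronger but
activation weaker -> silent.  The remaining quadrant (weaker binding,
stronger activation) has no defined class and raises.

Similarity profiles hold one percent-identity value per reference per class
for a chosen alignment scope (full length, peptide vs full reference, or
extracted N/C domain vs reference domain); class comparisons use Friedman +
Wilcoxon signed-rank (paired) or Kruskal-Wallis + Dunn/Bonferroni
(unpaired) on per-query class means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from . import seqcompare, stats_report
from .errors import InsufficientDataError, ParameterError, UnclassifiableError

CLASSES = ("stimulator", "silent", "evader")
SCOPES = ("full_length", "peptide", "n_domain", "c_domain")


def classify_reference(binding, activation, pim_binding, pim_activation):
    """Class label from TLR5 binding/activation readouts relative to the
    PIM reference.  Raises :class:`UnclassifiableError` on the undefined
    quadrant and on equality with the reference point."""
    for v in (binding, activation, pim_binding, pim_activation):
        if not np.isfinite(v):
            raise ParameterError("readouts must be finite")
    if binding == pim_binding or activation == pim_activation:
        raise UnclassifiableError(
            "readout equals the PIM reference; class undefined")
    if binding > pim_binding and activation > pim_activation:
        return "stimulator"
    if binding < pim_binding and activation < pim_activation:
        return "evader"
    if binding > pim_binding and activation < pim_activation:
        return "silent"
    raise UnclassifiableError(
        "weaker binding with stronger activation has no defined class")


@dataclass(frozen=True)
class ReferenceFlagellin:
    id: str
    sequence: str
    class_label: str
    n_domain: tuple | None = None
    c_domain: tuple | None = None
    binding: float | None = None
    activation: float | None = None

    def __post_init__(self):
        if self.class_label not in CLASSES:
            raise ParameterError(f"unknown class {self.class_label!r}")

    def domain_seq(self, scope):
        span = self.n_domain if scope == "n_domain" else self.c_domain
        if span is None:
            return None
        return self.sequence[span[0] - 1:span[1]]


def validate_reference(ref, pim_binding=1.0, pim_activation=1.0):
    """Check that a reference's label matches its readouts (when present)."""
    if ref.binding is None or ref.activation is None:
        return True
    return classify_reference(ref.binding, ref.activation, pim_binding,
                              pim_activation) == ref.class_label


@dataclass(frozen=True)
class ClassSimilarityProfile:
    query_id: str
    scope: str
    identity_to: dict = field(default_factory=dict)
    reference_ids: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scope not in SCOPES:
            raise ParameterError(f"unknown scope {self.scope!r}")
        if set(self.identity_to) != set(CLASSES):
            raise ParameterError("identity map keys must be the three classes")

    def class_mean(self, cls):
        return float(np.mean(self.identity_to[cls]))


def profile_similarity(query_id, query_sequence, references, scope,
                       query_n_domain=None, query_c_domain=None):
    """Percent identity of the query against every reference, grouped by
    reference class, under the requested alignment scope.

    Domain scopes align the query's annotated domain against each
    reference's corresponding domain; queries lacking the domain are skipped
    (returns ``None`` with a warning).  ``peptide`` aligns the (short) query
    locally against full references; ``full_length`` aligns globally.
    """
    if not references:
        raise ParameterError("reference list must be non-empty")
    if scope not in SCOPES:
        raise ParameterError(f"unknown scope {scope!r}")
    if scope in ("n_domain", "c_domain"):
        span = query_n_domain if scope == "n_domain" else query_c_domain
        if span is None:
            warnings.warn(f"query {query_id} lacks {scope}; skipped",
                          stacklevel=2)
            return None
        query_seq = query_sequence[span[0] - 1:span[1]]
    else:
        query_seq = query_sequence
    mode = "local" if scope == "peptide" else "global"
    identity_to = {cls: [] for cls in CLASSES}
    reference_ids = {cls: [] for cls in CLASSES}
    for ref in references:
        if scope in ("n_domain", "c_domain"):
            target = ref.domain_seq(scope)
            if target is None:
                continue
        else:
            target = ref.sequence
        result = seqcompare.align(query_seq, target, mode=mode,
                                  query_id=query_id, target_id=ref.id)
        identity_to[ref.class_label].append(
            result.identity_pct if result else 0.0)
        reference_ids[ref.class_label].append(ref.id)
    if any(len(v) == 0 for v in identity_to.values()):
        raise ParameterError(
            f"references must cover all three classes for scope {scope}")
    return ClassSimilarityProfile(query_id, scope, identity_to, reference_ids)


@dataclass(frozen=True)
class ClassComparisonReport:
    omnibus: stats_report.TestResult
    pairwise: pd.DataFrame
    class_means: dict
    n_queries: int
    paired: bool

    def contrast(self, cls_a, cls_b):
        """Row of the pairwise table for a class contrast, or None."""
        for _, row in self.pairwise.iterrows():
            if {row["class_i"], row["class_j"]} == {cls_a, cls_b}:
                return row
        return None


def _profile_matrix(profiles):
    rows = []
    ids = []
    for prof in profiles:
        rows.append([prof.class_mean(cls) for cls in CLASSES])
        ids.append(prof.query_id)
    return np.asarray(rows, dtype=float), ids


def compare_class_similarity(profiles, paired=True, alpha=0.05):
    """Compare per-query mean identity across the three reference classes.

    ``paired=True``: Friedman omnibus on (query x class) blocks, pairwise
    Wilcoxon signed-rank with Bonferroni adjustment.  ``paired=False``:
    Kruskal-Wallis + Dunn with Bonferroni.  Requires >= 3 query profiles.
    """
    profiles = list(profiles)
    if len(profiles) < 3:
        raise InsufficientDataError(
            f"need >= 3 query profiles, got {len(profiles)}")
    matrix, _ = _profile_matrix(profiles)
    class_means = {cls: float(matrix[:, i].mean())
                   for i, cls in enumerate(CLASSES)}
    pair_rows = []
    if paired:
        omnibus = stats_report.friedman(matrix)
        n_pairs = 3
        for i in range(3):
            for j in range(i + 1, 3):
                diff = matrix[:, i] - matrix[:, j]
                if np.all(diff == 0):
                    stat, p_raw = 0.0, 1.0
                else:
                    res = sps.wilcoxon(matrix[:, i], matrix[:, j],
                                       zero_method="wilcox")
                    stat, p_raw = float(res.statistic), float(res.pvalue)
                pair_rows.append({
                    "class_i": CLASSES[i], "class_j": CLASSES[j],
                    "statistic": stat, "p": min(max(p_raw, 1e-300), 1.0),
                    "p_adj": min(1.0, max(p_raw, 1e-300) * n_pairs),
                    "higher": CLASSES[i] if np.median(diff) > 0 else CLASSES[j],
                })
        pairwise = pd.DataFrame(pair_rows)
    else:
        omnibus, dunn = kruskal_dunn_classes(matrix, alpha=alpha)
        pairwise = dunn
    return ClassComparisonReport(omnibus, pairwise, class_means,
                                 len(profiles), paired)


def kruskal_dunn_classes(matrix, alpha=0.05):
    """Kruskal-Wallis + Dunn over the three class columns of a per-query
    mean-identity matrix, with class-name labelling."""
    groups = [matrix[:, i] for i in range(matrix.shape[1])]
    omnibus, dunn = stats_report.kruskal_dunn(groups, alpha=alpha)
    if len(dunn):
        dunn = dunn.assign(
            class_i=[CLASSES[i] for i in dunn["group_i"]],
            class_j=[CLASSES[j] for j in dunn["group_j"]],
            higher=[CLASSES[h] for h in dunn["higher"]],
        ).drop(columns=["group_i", "group_j"])
    else:
        dunn = pd.DataFrame(columns=["z", "p", "p_adj", "higher",
                                     "class_i", "class_j"])
    return omnibus, dunn


def bound_vs_unbound_contrast(bound_profiles, unbound_profiles, paired=False,
                              alpha=0.05):
    """Run the class-contrast battery on antibody-bound and never-bound
    flagellin profiles side by side.  The two sets must have disjoint query
    ids."""
    bound_profiles = list(bound_profiles)
    unbound_profiles = list(unbound_profiles)
    if not bound_profiles or not unbound_profiles:
        raise ParameterError("both profile sets must be non-empty")
    bound_ids = {p.query_id for p in bound_profiles}
    unbound_ids = {p.query_id for p in unbound_profiles}
    overlap = bound_ids & unbound_ids
    if overlap:
        raise ParameterError(
            f"bound and unbound sets share query ids: {sorted(overlap)[:3]}")
    return {
        "bound": compare_class_similarity(bound_profiles, paired=paired,
                                          alpha=alpha),
        "unbound": compare_class_similarity(unbound_profiles, paired=paired,
                                            alpha=alpha),
    }


def profiles_to_frame(profiles):
    """Long-format TSV-ready table: query, scope, class, reference,
    identity_pct."""
    rows = []
    for prof in profiles:
        for cls in CLASSES:
            for ref_id, ident in zip(prof.reference_ids[cls],
                                     prof.identity_to[cls]):
                rows.append({"query": prof.query_id, "scope": prof.scope,
                             "class": cls, "reference": ref_id,
                             "identity_pct": ident})
    return pd.DataFrame(rows)


def load_reference_set(fasta_path, meta_path):
    """References from FASTA plus sidecar TSV
    (id, class, binding, activation, n_start, n_end, c_start, c_end)."""
    seqs = {}
    name = None
    with open(fasta_path) as fh:
        for line in fh:
            line = line.strip()
            if line.startswith(">"):
                name = line[1:].split()[0].split("|")[0]
                seqs[name] = ""
            elif name:
                seqs[name] += line
    meta = pd.read_csv(meta_path, sep="\t")
    refs = []
    for _, row in meta.iterrows():
        rid = str(row["id"])
        if rid not in seqs:
            raise ParameterError(f"reference {rid} missing from FASTA")
        n_dom = None
        c_dom = None
        if not pd.isna(row.get("n_start")):
            n_dom = (int(row["n_start"]), int(row["n_end"]))
        if not pd.isna(row.get("c_start")):
            c_dom = (int(row["c_start"]), int(row["c_end"]))
        refs.append(ReferenceFlagellin(
            id=rid, sequence=seqs[rid], class_label=str(row["class"]),
            n_domain=n_dom, c_domain=c_dom,
            binding=None if pd.isna(row.get("binding")) else float(row["binding"]),
            activation=None if pd.isna(row.get("activation"))
            else float(row["activation"])))
    return refs
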