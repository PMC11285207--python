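"""Synthetic flagellin panels, peptide libraries, cohorts, and PhIP-Seq
count matrices with planted antibody-binding ground truth.

Flagellins are built as N-domain + hypervariable region + C-domain from a
fixed bundled template.  Class identity is encoded in two template variants:
evaders carry a divergent TLR5-motif sequence (conserved within the class),
silents carry a divergent C-terminal allosteric-site sequence; stimulators
track the template in both regions.  Hypervariable regions are i.i.d.
uniform over the 20 standard residues, drawn independently per flagellin.

Counts: library abundances are lognormal; input counts are multinomial over
those abundances; output counts are generalized Poisson with mean equal to
the input count for unbound cells, multiplied by a uniformly drawn
enrichment factor for bound (planted) cells.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import enrich, librarydesign
from .errors import ParameterError
from .librarydesign import PeptideTile, TilingParams

AA = "ACDEFGHIKLMNPQRSTVWY"
CLASSES = ("stimulator", "silent", "evader")


@dataclass(frozen=True)
class FlagellinTemplate:
    """Fixed flagellin scaffold with region annotations (1-based inclusive
    spans within each domain sequence)."""

    n_domain_seq: str
    tlr5_motif_span: tuple
    hinge_span: tuple
    hv_length_range: tuple
    c_domain_seq: str
    c_allosteric_span: tuple
    tlr5_motif_alt_seq: str = ""
    c_allosteric_alt_seq: str = ""

    def __post_init__(self):
        for span, seq, name in ((self.tlr5_motif_span, self.n_domain_seq, "motif"),
                                (self.hinge_span, self.n_domain_seq, "hinge"),
                                (self.c_allosteric_span, self.c_domain_seq,
                                 "allosteric")):
            lo, hi = span
            if not (1 <= lo <= hi <= len(seq)):
                raise ParameterError(f"{name} span {span} outside its domain")
        if self.hv_length_range[0] > self.hv_length_range[1]:
            raise ParameterError("bad hv_length_range")

    @property
    def motif_seq(self):
        lo, hi = self.tlr5_motif_span
        return self.n_domain_seq[lo - 1:hi]

    @property
    def allosteric_seq(self):
        lo, hi = self.c_allosteric_span
        return self.c_domain_seq[lo - 1:hi]


def default_template():
    """Load the bundled template (N domain ~135 aa, C domain ~85 aa, plus
    the evader-motif and silent-allosteric class variants)."""
    ref = importlib.resources.files("flagseq.data") / "flagellin_template.fasta"
    records = {}
    name = None
    for line in ref.read_text().splitlines():
        if line.startswith(">"):
            name = line[1:].split()[0]
            records[name] = ""
        elif name:
            records[name] += line.strip()
    return FlagellinTemplate(
        n_domain_seq=records["N_DOMAIN"],
        tlr5_motif_span=(79, 117),
        hinge_span=(31, 52),
        hv_length_range=(120, 220),
        c_domain_seq=records["C_DOMAIN"],
        c_allosteric_span=(45, 80),
        tlr5_motif_alt_seq=records["TLR5_MOTIF_ALT"],
        c_allosteric_alt_seq=records["C_ALLOSTERIC_ALT"],
    )


@dataclass(frozen=True)
class SyntheticFlagellin:
    id: str
    sequence: str
    true_class: str
    true_n_domain: tuple
    true_c_domain: tuple
    source_template: str = "default"

    def __post_init__(self):
        n_lo, n_hi = self.true_n_domain
        c_lo, c_hi = self.true_c_domain
        if not (1 == n_lo <= n_hi < c_lo <= c_hi == len(self.sequence)):
            raise ParameterError("domain coordinates are inconsistent")

    @property
    def n_domain_seq(self):
        return self.sequence[self.true_n_domain[0] - 1:self.true_n_domain[1]]

    @property
    def c_domain_seq(self):
        return self.sequence[self.true_c_domain[0] - 1:self.true_c_domain[1]]


@dataclass(frozen=True)
class MutationRates:
    """Per-region substitution probabilities applied to each class's base
    sequence (class divergence itself comes from the template variants)."""

    n_background: float = 0.02
    motif: float = 0.05
    hinge: float = 0.05
    c_background: float = 0.02
    allosteric: float = 0.05

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not (0 <= value <= 1):
                raise ParameterError(f"mutation rate {name}={value} not in [0, 1]")


def _mutate(seq, rate, rng):
    if rate == 0:
        return seq
    out = list(seq)
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        alternatives = [a for a in AA if a != seq[i]]
        out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


def _splice(seq, span, piece):
    lo, hi = span
    return seq[:lo - 1] + piece + seq[hi:]


def _regions(length, *spans):
    """Boolean mask of positions outside all given 1-based spans."""
    mask = np.ones(length, dtype=bool)
    for lo, hi in spans:
        mask[lo - 1:hi] = False
    return mask


def _mutate_regions(seq, spans_rates, background_rate, rng):
    """Mutate each 1-based span at its own rate, the rest at background."""
    out = list(seq)
    covered = np.zeros(len(seq), dtype=bool)
    for (lo, hi), rate in spans_rates:
        piece = _mutate(seq[lo - 1:hi], rate, rng)
        out[lo - 1:hi] = list(piece)
        covered[lo - 1:hi] = True
    for i in np.nonzero(~covered)[0]:
        if rng.random() < background_rate:
            alternatives = [a for a in AA if a != seq[i]]
            out[i] = alternatives[rng.integers(len(alternatives))]
    return "".join(out)


#: Extra divergence for the evader C-terminal allosteric region (pathogen
#: C domains are not class-conserved in this model).
EVADER_ALLOSTERIC_RATE = 0.30


def generate_reference_panel(template=None, n_per_class=20,
                             mutation_rates=MutationRates(), seed=0):
    """Generate ``n_per_class`` flagellins per class with known domains.

    Stimulators are near-template copies; silents conserve the TLR5 motif but
    carry the divergent allosteric variant in the C domain; evaders carry the
    divergent TLR5-motif variant.  Deterministic per seed.
    """
    if template is None:
        template = default_template()
    if n_per_class < 1:
        raise ParameterError("n_per_class must be >= 1")
    rng = np.random.default_rng(seed)
    panel = []
    for cls in CLASSES:
        n_base = template.n_domain_seq
        c_base = template.c_domain_seq
        allo_rate = mutation_rates.allosteric
        motif_rate = mutation_rates.motif
        hinge_rate = mutation_rates.hinge
        if cls == "stimulator":
            # Stimulators are near-template copies: low mutation everywhere.
            motif_rate = min(motif_rate, mutation_rates.n_background)
            hinge_rate = min(hinge_rate, mutation_rates.n_background)
            allo_rate = min(allo_rate, mutation_rates.c_background)
        if cls == "evader":
            n_base = _splice(n_base, template.tlr5_motif_span,
                             template.tlr5_motif_alt_seq)
            allo_rate = max(allo_rate, EVADER_ALLOSTERIC_RATE)
        if cls == "silent":
            c_base = _splice(c_base, template.c_allosteric_span,
                             template.c_allosteric_alt_seq)
        for i in range(n_per_class):
            n_seq = _mutate_regions(
                n_base,
                [(template.tlr5_motif_span, motif_rate),
                 (template.hinge_span, hinge_rate)],
                mutation_rates.n_background, rng)
            c_seq = _mutate_regions(
                c_base,
                [(template.c_allosteric_span, allo_rate)],
                mutation_rates.c_background, rng)
            hv_len = int(rng.integers(template.hv_length_range[0],
                                      template.hv_length_range[1] + 1))
            hv = "".join(np.array(list(AA))[rng.integers(0, len(AA), hv_len)])
            seq = n_seq + hv + c_seq
            panel.append(SyntheticFlagellin(
                id=f"{cls[:4]}_{i:03d}",
                sequence=seq,
                true_class=cls,
                true_n_domain=(1, len(n_seq)),
                true_c_domain=(len(seq) - len(c_seq) + 1, len(seq)),
            ))
    return panel


def assign_tlr5_readouts(panel, seed=0, pim_binding=1.0, pim_activation=1.0):
    """Synthetic TLR5 binding/activation readouts consistent with each
    flagellin's class, relative to the FliC-PIM-like reference point."""
    rng = np.random.default_rng(seed)
    rows = []
    for flg in panel:
        hi_b = pim_binding * rng.uniform(1.5, 5.0)
        hi_a = pim_activation * rng.uniform(1.5, 5.0)
        lo_b = pim_binding * rng.uniform(0.1, 0.7)
        lo_a = pim_activation * rng.uniform(0.1, 0.7)
        if flg.true_class == "stimulator":
            binding, activation = hi_b, hi_a
        elif flg.true_class == "silent":
            binding, activation = hi_b, lo_a
        else:
            binding, activation = lo_b, lo_a
        rows.append({"id": flg.id, "class": flg.true_class,
                     "binding": binding, "activation": activation})
    return pd.DataFrame(rows).set_index("id")


# ---------------------------------------------------------------------------
# Library generation
# ---------------------------------------------------------------------------

def _overlap_frac(tile_start, tile_end, span):
    lo, hi = span
    inter = min(tile_end, hi) - max(tile_start, lo) + 1
    return max(inter, 0) / (tile_end - tile_start + 1)


def generate_library(panel, n_nonflagellin=200, tiling_params=TilingParams(),
                     seed=0, nonflagellin_length_range=(150, 800)):
    """Tile the flagellin panel plus random non-flagellin proteins.

    Returns ``(tiles, annotations)`` where annotations is a DataFrame indexed
    by peptide id with parent, span, flagellin flag, parent class and the
    tile's overlap fraction with the parent's true N/C domains.
    """
    if not panel:
        raise ParameterError("panel must be non-empty")
    if n_nonflagellin < 0:
        raise ParameterError("n_nonflagellin must be >= 0")
    rng = np.random.default_rng(seed)
    proteins = [(f.id, f.sequence, f) for f in panel]
    for i in range(n_nonflagellin):
        length = int(rng.integers(*nonflagellin_length_range))
        seq = "".join(np.array(list(AA))[rng.integers(0, len(AA), length)])
        proteins.append((f"prot_{i:04d}", seq, None))

    tiles = []
    rows = []
    counter = 0
    for parent_id, seq, flg in proteins:
        for tile in librarydesign.tile_protein(seq, tiling_params,
                                               parent_id=parent_id):
            pid = f"pep_{counter:06d}"
            counter += 1
            tile = PeptideTile(pid, parent_id, tile.start, tile.end,
                               tile.sequence)
            tiles.append(tile)
            row = {"peptide_id": pid, "parent_id": parent_id,
                   "start": tile.start, "end": tile.end,
                   "length": tile.end - tile.start + 1,
                   "parent_length": len(seq),
                   "is_flagellin": flg is not None,
                   "parent_class": flg.true_class if flg else "none",
                   "n_overlap_frac": 0.0, "c_overlap_frac": 0.0}
            if flg is not None:
                row["n_overlap_frac"] = _overlap_frac(tile.start, tile.end,
                                                      flg.true_n_domain)
                row["c_overlap_frac"] = _overlap_frac(tile.start, tile.end,
                                                      flg.true_c_domain)
            rows.append(row)
    annotations = pd.DataFrame(rows).set_index("peptide_id")
    return tiles, annotations


# ---------------------------------------------------------------------------
# Cohort design and count simulation
# ---------------------------------------------------------------------------

DEFAULT_AGE_BINS = {"20-24": 0.1, "25-29": 0.15, "30-34": 0.2, "35-39": 0.2,
                    "40-44": 0.15, "45-49": 0.1, "50-54": 0.1}


@dataclass(frozen=True)
class CohortDesign:
    """Matched case/control cohort with planted per-signature binding."""

    n_cases: int = 40
    n_controls: int = 40
    age_group_distribution: dict = field(
        default_factory=lambda: dict(DEFAULT_AGE_BINS))
    sex_distribution: float = 0.5
    planted_peptide_sets: dict = field(default_factory=dict)
    case_binding_prevalence: dict = field(default_factory=dict)
    control_binding_prevalence: dict = field(default_factory=dict)
    peptide_binding_probs: dict = field(default_factory=dict)
    enrichment_factor_range: tuple = (10.0, 50.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_cases <= 0 or self.n_controls <= 0:
            raise ParameterError("cohort sizes must be positive")
        if not (0 <= self.sex_distribution <= 1):
            raise ParameterError("sex_distribution must be a fraction")
        for prev in (self.case_binding_prevalence,
                     self.control_binding_prevalence):
            for name, value in prev.items():
                if not (0 <= value <= 1):
                    raise ParameterError(
                        f"prevalence {name}={value} not in [0, 1]")
        lo, hi = self.enrichment_factor_range
        if not (1 <= lo <= hi):
            raise ParameterError("enrichment factors must be >= 1")


@dataclass(frozen=True)
class SimulatedCounts:
    input_counts: pd.DataFrame
    output_counts: pd.DataFrame
    truth_bound: pd.DataFrame
    gp_dispersion: float
    metadata: pd.DataFrame


def simulate_counts(tiles, design, total_reads_per_sample=200_000,
                    gp_dispersion=0.2):
    """Simulate input/output count matrices for a designed cohort.

    Input counts per sample are multinomial draws over lognormal library
    abundances.  Output counts are generalized Poisson with dispersion
    ``gp_dispersion``; the GP rate is ``input * (1 - lam)`` for unbound
    cells (mean equal to the input count) and is multiplied by a uniformly
    drawn enrichment factor for bound cells.  Fully deterministic per
    ``design.seed``.
    """
    if not (0 <= gp_dispersion < 1):
        raise ParameterError("gp_dispersion must be in [0, 1)")
    if total_reads_per_sample <= 0:
        raise ParameterError("total_reads_per_sample must be positive")
    peptide_ids = [t.peptide_id for t in tiles]
    pep_index = {p: i for i, p in enumerate(peptide_ids)}
    for name, peps in design.planted_peptide_sets.items():
        unknown = [p for p in peps if p not in pep_index]
        if unknown:
            raise ParameterError(
                f"signature {name!r} references unknown peptides: "
                f"{unknown[:3]}...")
    rng = np.random.default_rng(design.seed)
    n_pep = len(peptide_ids)

    # Cohort metadata.
    sample_ids = ([f"case_{i:03d}" for i in range(design.n_cases)]
                  + [f"ctrl_{i:03d}" for i in range(design.n_controls)])
    groups = ["case"] * design.n_cases + ["control"] * design.n_controls
    age_bins = list(design.age_group_distribution)
    age_w = np.array([design.age_group_distribution[b] for b in age_bins],
                     dtype=float)
    age_w = age_w / age_w.sum()
    ages = [age_bins[i] for i in rng.choice(len(age_bins), size=len(sample_ids),
                                            p=age_w)]
    sexes = np.where(rng.random(len(sample_ids)) < design.sex_distribution,
                     "F", "M")
    metadata = pd.DataFrame({"sample_id": sample_ids, "group": groups,
                             "age_bin": ages, "sex": sexes}).set_index("sample_id")

    # Library abundances and input counts.
    abundance = rng.lognormal(mean=0.0, sigma=1.0, size=n_pep)
    probs = abundance / abundance.sum()
    input_mat = np.empty((n_pep, len(sample_ids)), dtype=np.int64)
    for j in range(len(sample_ids)):
        input_mat[:, j] = rng.multinomial(total_reads_per_sample, probs)

    # Planted binding truth.
    bound = np.zeros((n_pep, len(sample_ids)), dtype=bool)
    for name, peps in sorted(design.planted_peptide_sets.items()):
        rows = np.array([pep_index[p] for p in peps], dtype=int)
        attach = np.array(
            [design.peptide_binding_probs.get(name, {}).get(p, 1.0)
             for p in peps])
        case_prev = design.case_binding_prevalence.get(name, 0.0)
        ctrl_prev = design.control_binding_prevalence.get(name, 0.0)
        for j, group in enumerate(groups):
            prev = case_prev if group == "case" else ctrl_prev
            if rng.random() < prev:
                # Carriers share a per-sample antibody "breadth": a carrier
                # binds every signature peptide whose attachment probability
                # exceeds its breadth draw.  Marginally each peptide is bound
                # with its attachment probability, but per-peptide prevalences
                # are rank-concordant across cohorts (broad sera bind
                # supersets of what narrow sera bind).
                breadth = rng.random()
                hit = attach >= breadth
                bound[rows[hit], j] = True

    # Output counts.
    lam = gp_dispersion
    factors = np.ones((n_pep, len(sample_ids)))
    lo, hi = design.enrichment_factor_range
    n_bound = int(bound.sum())
    if n_bound:
        factors[bound] = rng.uniform(lo, hi, size=n_bound)
    theta = input_mat * (1.0 - lam) * factors
    output_mat = enrich.gp_rvs(theta, lam, rng)

    input_counts = pd.DataFrame(input_mat, index=peptide_ids,
                                columns=sample_ids)
    output_counts = pd.DataFrame(output_mat, index=peptide_ids,
                                 columns=sample_ids)
    truth = pd.DataFrame(bound, index=peptide_ids, columns=sample_ids)
    return SimulatedCounts(input_counts, output_counts, truth, lam, metadata)


# ---------------------------------------------------------------------------
# External interfaces
# ---------------------------------------------------------------------------

def write_library_fasta(tiles, annotations, path):
    """Write peptides as FASTA with
    ``>peptideID|parentID|start|end|flagellin={0,1}`` headers."""
    with open(path, "w") as fh:
        for t in tiles:
            flag = int(annotations.loc[t.peptide_id, "is_flagellin"])
            fh.write(f">{t.peptide_id}|{t.parent_id}|{t.start}|{t.end}|"
                     f"flagellin={flag}\n{t.sequence}\n")


def write_run_outputs(sim, outdir, tiles=None, annotations=None,
                      manifest=None):
    """Write count matrices, metadata, truth table, and optionally the
    library FASTA and a YAML manifest of generation parameters."""
    import pathlib

    import yaml

    outdir = pathlib.Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim.input_counts.to_csv(outdir / "input.tsv", sep="\t",
                            index_label="peptide_id")
    sim.output_counts.to_csv(outdir / "output.tsv", sep="\t",
                             index_label="peptide_id")
    sim.metadata.to_csv(outdir / "metadata.tsv", sep="\t")
    sim.truth_bound.astype(int).to_csv(outdir / "truth.tsv", sep="\t",
                                       index_label="peptide_id")
    if tiles is not None and annotations is not None:
        write_library_fasta(tiles, annotations, outdir / "library.fasta")
        annotations.to_csv(outdir / "library_annotations.tsv", sep="\t")
    if manifest is not None:
        with open(outdir / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=True)
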