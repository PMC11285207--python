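import numpy as np
import pytest

from flagseq import enrich, synthgen
from flagseq.errors import ParameterError
from flagseq.librarydesign import TilingParams


def hamming(a, b):
    assert len(a) == len(b)
    return sum(x != y for x, y in zip(a, b))


class TestTemplate:
    def test_bundled_template_geometry(self, template):
        assert 130 <= len(template.n_domain_seq) <= 140
        assert 80 <= len(template.c_domain_seq) <= 90
        lo, hi = template.tlr5_motif_span
        assert 1 <= lo <= hi <= len(template.n_domain_seq)
        assert len(template.tlr5_motif_alt_seq) == hi - lo + 1

    def test_bad_span_raises(self, template):
        with pytest.raises(ParameterError):
            synthgen.FlagellinTemplate(
                n_domain_seq="ACDEF", tlr5_motif_span=(2, 9),
                hinge_span=(1, 2), hv_length_range=(5, 10),
                c_domain_seq="ACDEF", c_allosteric_span=(1, 3))


class TestReferencePanel:
    def test_zero_mutation_stimulator_equals_template(self, template):
        rates = synthgen.MutationRates(0, 0, 0, 0, 0)
        panel = synthgen.generate_reference_panel(template, n_per_class=2,
                                                  mutation_rates=rates, seed=0)
        stim = [f for f in panel if f.true_class == "stimulator"][0]
        assert stim.n_domain_seq == template.n_domain_seq
        assert stim.c_domain_seq == template.c_domain_seq

    def test_evader_motif_distance_exceeds_stimulators(self, template):
        rates = synthgen.MutationRates(motif=0.5)
        panel = synthgen.generate_reference_panel(template, n_per_class=6,
                                                  mutation_rates=rates, seed=1)
        lo, hi = template.tlr5_motif_span
        motif = template.motif_seq

        def motif_of(flg):
            return flg.n_domain_seq[lo - 1:hi]

        stim_d = [hamming(motif_of(f), motif) for f in panel
                  if f.true_class == "stimulator"]
        evad_d = [hamming(motif_of(f), motif) for f in panel
                  if f.true_class == "evader"]
        assert min(evad_d) > max(stim_d)

    def test_determinism(self, template):
        a = synthgen.generate_reference_panel(template, n_per_class=4, seed=9)
        b = synthgen.generate_reference_panel(template, n_per_class=4, seed=9)
        assert a == b

    def test_sequence_reconstruction_invariant(self, panel):
        for flg in panel:
            n = flg.sequence[flg.true_n_domain[0] - 1:flg.true_n_domain[1]]
            c = flg.sequence[flg.true_c_domain[0] - 1:flg.true_c_domain[1]]
            hv = flg.sequence[flg.true_n_domain[1]:flg.true_c_domain[0] - 1]
            assert n + hv + c == flg.sequence
            assert flg.true_c_domain[1] == len(flg.sequence)

    def test_bad_mutation_rate_raises(self):
        with pytest.raises(ParameterError):
            synthgen.MutationRates(motif=1.5)

    def test_class_separability_by_motif_identity(self, template):
        panel = synthgen.generate_reference_panel(template, n_per_class=10,
                                                  seed=3)
        lo, hi = template.tlr5_motif_span
        motif = template.motif_seq

        def mean_identity(cls):
            members = [f for f in panel if f.true_class == cls]
            return np.mean([1 - hamming(f.n_domain_seq[lo - 1:hi], motif)
                            / len(motif) for f in members])

        stim, silent, evader = (mean_identity(c) for c in
                                ("stimulator", "silent", "evader"))
        assert stim >= silent
        assert silent > evader + 0.2

    def test_readouts_consistent_with_class(self, panel):
        readouts = synthgen.assign_tlr5_readouts(panel, seed=4)
        for flg in panel:
            b = readouts.loc[flg.id, "binding"]
            a = readouts.loc[flg.id, "activation"]
            if flg.true_class == "stimulator":
                assert b > 1 and a > 1
            elif flg.true_class == "silent":
                assert b > 1 and a < 1
            else:
                assert b < 1 and a < 1


class TestGenerateLibrary:
    def test_single_protein_single_tile(self, template):
        panel = [synthgen.SyntheticFlagellin(
            "f0", "A" * 40 + "C" * 14 + "D" * 10, "stimulator",
            (1, 40), (55, 64))]
        tiles, annot = synthgen.generate_library(panel, n_nonflagellin=0,
                                                 seed=0)
        assert len(tiles) == 1
        assert annot["is_flagellin"].all()

    def test_first_tile_full_n_overlap(self, panel):
        tiles, annot = synthgen.generate_library(panel, n_nonflagellin=0,
                                                 seed=0)
        flg = panel[0]
        first = annot[(annot["parent_id"] == flg.id)
                      & (annot["start"] == 1)].iloc[0]
        # true N domain is 135 aa, tile is 64 aa: fully inside -> overlap 1.0
        assert first["n_overlap_frac"] == pytest.approx(64 / 64)

    def test_empty_panel_raises(self):
        with pytest.raises(ParameterError):
            synthgen.generate_library([], n_nonflagellin=5, seed=0)

    def test_tiles_match_librarydesign(self, panel):
        from flagseq import librarydesign
        tiles, _ = synthgen.generate_library(panel, n_nonflagellin=0, seed=0)
        expected = []
        for flg in panel:
            expected.extend((flg.id, t.start, t.end) for t in
                            librarydesign.tile_protein(flg.sequence,
                                                       TilingParams()))
        assert [(t.parent_id, t.start, t.end) for t in tiles] == expected


class TestSimulateCounts:
    def test_zero_planted_sets_truth_all_false(self, library):
        tiles, _ = library
        design = synthgen.CohortDesign(n_cases=3, n_controls=3, seed=0)
        sim = synthgen.simulate_counts(tiles, design,
                                       total_reads_per_sample=20_000)
        assert not sim.truth_bound.to_numpy().any()

    def test_shapes_and_metadata(self, library):
        tiles, _ = library
        design = synthgen.CohortDesign(n_cases=5, n_controls=4, seed=1)
        sim = synthgen.simulate_counts(tiles, design,
                                       total_reads_per_sample=20_000)
        assert sim.input_counts.shape == sim.output_counts.shape
        assert sim.input_counts.shape == (len(tiles), 9)
        assert (sim.input_counts.sum(axis=0) == 20_000).all()
        assert list(sim.metadata["group"]) == ["case"] * 5 + ["control"] * 4

    def test_determinism(self, library):
        tiles, _ = library
        design = synthgen.CohortDesign(n_cases=3, n_controls=3, seed=5)
        a = synthgen.simulate_counts(tiles, design, 20_000)
        b = synthgen.simulate_counts(tiles, design, 20_000)
        assert a.output_counts.equals(b.output_counts)
        assert a.metadata.equals(b.metadata)

    def test_bad_dispersion_raises(self, library):
        tiles, _ = library
        design = synthgen.CohortDesign(seed=0)
        with pytest.raises(ParameterError):
            synthgen.simulate_counts(tiles, design, gp_dispersion=1.0)

    def test_enrichment_factor_scales_output_mean(self, rng):
        """Enrichment factor 50 multiplies the unbound GP mean, checked by a
        direct sample-mean oracle at 1,000 replicates."""
        lam = 0.2
        inp = 100.0
        factor = 50.0
        unbound = enrich.gp_rvs(np.full(1000, inp * (1 - lam)), lam, rng)
        bound = enrich.gp_rvs(np.full(1000, inp * (1 - lam) * factor), lam,
                              rng)
        assert bound.mean() / unbound.mean() == pytest.approx(50.0, rel=0.1)

    def test_enrichment_factor_one_indistinguishable(self, library):
        """With enrichment factors pinned at 1, bound cells follow the null;
        downstream seropositivity stays at the familywise alpha level."""
        tiles, annot = library
        peps = list(annot.index[:50])
        design = synthgen.CohortDesign(
            n_cases=10, n_controls=10, seed=7,
            planted_peptide_sets={"s": peps},
            case_binding_prevalence={"s": 1.0},
            control_binding_prevalence={"s": 1.0},
            enrichment_factor_range=(1.0, 1.0))
        sim = synthgen.simulate_counts(tiles, design,
                                       total_reads_per_sample=50_000)
        assert sim.truth_bound.loc[peps].all().all()
        calls, _ = enrich.score_matrix(sim.input_counts, sim.output_counts,
                                       floor=0, min_enriched=0,
                                       min_bin_obs=100)
        fp = calls.groupby("sample_id")["seropositive"].sum()
        assert (fp > 0).mean() <= 0.1  # 20 samples; at most 2 with any call

    def test_cohort_balance_over_seeds(self, library):
        """Age/sex are drawn from identical distributions for cases and
        controls; the balance check should pass for >= 90% of seeds."""
        from flagseq import stats_report
        tiles, _ = library
        ok = 0
        n_seeds = 20
        for seed in range(100, 100 + n_seeds):
            design = synthgen.CohortDesign(n_cases=25, n_controls=25,
                                           seed=seed)
            sim = synthgen.simulate_counts(tiles[:5], design,
                                           total_reads_per_sample=500)
            age_test, sex_test = stats_report.cohort_balance_check(
                sim.metadata)
            if age_test.p > 0.05 and sex_test.p > 0.05:
                ok += 1
        assert ok >= 0.9 * n_seeds

    def test_unknown_planted_peptide_raises(self, library):
        tiles, _ = library
        design = synthgen.CohortDesign(
            n_cases=2, n_controls=2, seed=0,
            planted_peptide_sets={"s": ["nonexistent"]},
            case_binding_prevalence={"s": 0.5})
        with pytest.raises(ParameterError):
            synthgen.simulate_counts(tiles, design, 1000)


def test_write_run_outputs_round_trip(tmp_path, library):
    import pandas as pd
    tiles, annot = library
    design = synthgen.CohortDesign(n_cases=2, n_controls=2, seed=3)
    sim = synthgen.simulate_counts(tiles, design, 10_000)
    synthgen.write_run_outputs(sim, tmp_path, tiles=tiles, annotations=annot,
                               manifest={"seed": 3})
    read_back = pd.read_csv(tmp_path / "input.tsv", sep="\t", index_col=0)
    assert read_back.equals(sim.input_counts)
    fasta = (tmp_path / "library.fasta").read_text().splitlines()
    assert fasta[0].startswith(">pep_000000|")
    assert "flagellin=1" in fasta[0]
    assert (tmp_path / "manifest.yaml").exists()
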