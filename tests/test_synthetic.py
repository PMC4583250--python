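"""Synthetic generator: determinism, truth labelling, filter recovery."""

import numpy as np
import pytest
from scipy import stats

from mitoburden.core_model import MitoGeneModel
from mitoburden.errors import ValidationError
from mitoburden.filtering import aggregate, genotype_filter, strand_balance_filter
from mitoburden.synthetic import (
    SimConfig,
    homopolymer_runs,
    make_paper_fixture,
    make_toy_genome,
    simulate_bundle,
    simulate_calls,
    simulate_population,
)

SMALL = SimConfig(
    genome_length=4000,
    n_samples=50,
    n_common_variants=20,
    n_rare_variants=60,
    n_ref_minor_sites=2,
    mean_depth=60.0,
    seed=11,
)


class TestMakeToyGenome:
    def test_structural_guarantees(self):
        genome, model = make_toy_genome(SMALL)
        assert genome.length == SMALL.genome_length
        biotypes = {g.biotype for g in model}
        assert {"protein_coding", "Mt_rRNA", "Mt_tRNA"} <= biotypes
        assert any(g.strand == "-" for g in model)
        # at least one overlapping pair
        overlaps = [
            (a.symbol, b.symbol)
            for i, a in enumerate(model)
            for b in list(model)[i + 1 :]
            if any(b.contains(p) for p in (a.start, a.end))
            or any(a.contains(p) for p in (b.start, b.end))
        ]
        assert overlaps
        assert len(homopolymer_runs(genome, 4)) >= 3

    def test_deterministic_under_seed(self):
        g1, m1 = make_toy_genome(SMALL)
        g2, m2 = make_toy_genome(SMALL)
        assert g1.sequence == g2.sequence
        assert m1.genes == m2.genes
        g3, _ = make_toy_genome(SimConfig(**{**SMALL.__dict__, "seed": 12}))
        assert g3.sequence != g1.sequence

    def test_too_small_genome_rejected(self):
        with pytest.raises(ValidationError):
            SimConfig(genome_length=500)


class TestSimulatePopulation:
    def test_rare_variant_carrier_bounds(self):
        genome, _ = make_toy_genome(SMALL)
        cfg = SimConfig(**{**SMALL.__dict__, "n_common_variants": 0, "n_ref_minor_sites": 0})
        truth = simulate_population(cfg, genome)
        assert len(truth.keys) == cfg.n_rare_variants
        assert all(1 <= truth.carrier_count(k) <= 3 for k in truth.keys)

    def test_ref_minor_sites_carried_by_95pct(self):
        genome, _ = make_toy_genome(SMALL)
        cfg = SimConfig(
            **{**SMALL.__dict__, "n_samples": 436, "n_common_variants": 0,
               "n_rare_variants": 0, "n_ref_minor_sites": 2}
        )
        truth = simulate_population(cfg, genome)
        assert len(truth.keys) == 2
        for k in truth.keys:
            assert truth.carrier_count(k) >= int(np.ceil(0.95 * 436))

    def test_zero_variants(self):
        genome, _ = make_toy_genome(SMALL)
        cfg = SimConfig(
            **{**SMALL.__dict__, "n_common_variants": 0, "n_rare_variants": 0,
               "n_ref_minor_sites": 0}
        )
        assert simulate_population(cfg, genome).keys == []

    def test_keys_unique_and_ref_matches_sequence(self):
        genome, _ = make_toy_genome(SMALL)
        truth = simulate_population(SMALL, genome)
        keys = truth.keys
        assert len(keys) == len(set(keys))
        for k in keys[:50]:
            assert genome.base(k.position) == k.ref


class TestSimulateCalls:
    def test_labels_cover_all_calls(self):
        genome, _ = make_toy_genome(SMALL)
        truth = simulate_population(SMALL, genome)
        calls, labels = simulate_calls(truth, SMALL, genome)
        assert len(calls) == len(labels)
        assert all(
            l.sample_id == c.sample_id and l.key == c.key
            for c, l in zip(calls, labels)
        )

    def test_rate_zero_means_no_artifacts(self):
        genome, _ = make_toy_genome(SMALL)
        cfg = SimConfig(
            **{**SMALL.__dict__, "het_artifact_rate": 0.0,
               "strand_artifact_rate": 0.0, "homopolymer_indel_rate": 0.0}
        )
        truth = simulate_population(cfg, genome)
        _, labels = simulate_calls(truth, cfg, genome)
        assert {l.label for l in labels} == {"true_variant"}

    def test_het_fraction_within_binomial_bounds(self):
        genome, _ = make_toy_genome(SMALL)
        cfg = SimConfig(
            **{**SMALL.__dict__, "n_common_variants": 40, "het_artifact_rate": 0.1,
               "strand_artifact_rate": 0.0, "homopolymer_indel_rate": 0.0}
        )
        truth = simulate_population(cfg, genome)
        _, labels = simulate_calls(truth, cfg, genome)
        n_true = sum(l.label == "true_variant" for l in labels)
        n_het = sum(l.label == "het_artifact" for l in labels)
        lo, hi = stats.binom.interval(0.99, n_true, 0.1)
        assert lo <= n_het <= hi

    def test_strand_artifacts_single_stranded(self):
        genome, _ = make_toy_genome(SMALL)
        truth = simulate_population(SMALL, genome)
        calls, labels = simulate_calls(truth, SMALL, genome)
        for c, l in zip(calls, labels):
            if l.label == "strand_artifact":
                assert min(c.alt_fwd, c.alt_rev) == 0
                assert max(c.alt_fwd, c.alt_rev) > 0

    def test_homopolymer_artifacts_are_indels_in_runs(self):
        genome, _ = make_toy_genome(SMALL)
        cfg = SimConfig(**{**SMALL.__dict__, "homopolymer_indel_rate": 0.05})
        truth = simulate_population(cfg, genome)
        calls, labels = simulate_calls(truth, cfg, genome)
        run_pos = {p for s, e in homopolymer_runs(genome, 4) for p in range(s, e + 1)}
        hits = [c for c, l in zip(calls, labels) if l.label == "homopolymer_artifact"]
        assert hits
        for c in hits:
            assert len(c.ref) != len(c.alt)
            assert c.position in run_pos


class TestFilterRecovery:
    def test_end_to_end_artifact_removal_and_carrier_recovery(self):
        genome, _ = make_toy_genome(SMALL)
        truth = simulate_population(SMALL, genome)
        calls, labels = simulate_calls(truth, SMALL, genome)
        gt_pass, _ = genotype_filter(calls)
        sb_pass, _ = strand_balance_filter(gt_pass, 0.10)
        variants = {v.key: v for v in aggregate(sb_pass)}

        kept_artifacts = [
            l for l in labels
            if l.label in ("het_artifact", "strand_artifact") and l.key in variants
        ]
        assert kept_artifacts == []

        # every true call with balanced support survives; carrier counts match
        expected = {}
        for c, l in zip(calls, labels):
            if l.label != "true_variant":
                continue
            total = c.alt_fwd + c.alt_rev
            if total > 0 and min(c.alt_fwd, c.alt_rev) / total >= 0.10:
                expected.setdefault(c.key, set()).add(c.sample_id)
        for key, samples in expected.items():
            assert key in variants, key
            assert variants[key].carrier_count == len(samples)


class TestEnrichmentRankRecovery:
    def test_denser_gene_ranks_higher_in_95pct_of_replicates(self):
        """Two genes with per-base variant densities 5x apart: the denser one
        must have the larger estimated r_g in at least 95 of 100 replicates."""
        base = SimConfig(
            genome_length=2500,
            n_genes=6,
            n_samples=30,
            n_common_variants=0,
            n_rare_variants=0,
            n_ref_minor_sites=0,
            mean_depth=40.0,
            seed=100,
        )
        genome, model = make_toy_genome(base)
        dense, sparse = "PC01", "PC03"
        densities = {dense: 0.05, sparse: 0.01}
        wins = 0
        for rep in range(100):
            cfg = SimConfig(**{**base.__dict__, "seed": 1000 + rep})
            truth = simulate_population(cfg, genome, gene_densities=densities, model=model)
            counts = {dense: 0, sparse: 0}
            for k in truth.keys:
                for sym in (dense, sparse):
                    if model[sym].contains(k.position):
                        counts[sym] += 1
            rg = {
                sym: counts[sym] / model[sym].printed_length * 1000
                for sym in (dense, sparse)
            }
            if rg[dense] > rg[sparse]:
                wins += 1
        assert wins >= 95


class TestBundleDeterminism:
    def test_byte_identical_reruns(self, tmp_path):
        p1 = simulate_bundle(SMALL, tmp_path / "a")
        p2 = simulate_bundle(SMALL, tmp_path / "b")
        for name in p1:
            assert p1[name].read_bytes() == p2[name].read_bytes(), name


class TestPaperFixture:
    def test_row_counts_and_key_overlap(self, paper_fixture):
        assert len(paper_fixture.concordant) == 24
        assert len(paper_fixture.unknown) == 35
        assert len(paper_fixture.gene_table) == 15
        conc_keys = {
            (int(r["position"]), r["ref"], r["alt"])
            for _, r in paper_fixture.concordant.iterrows()
        }
        unk_keys = {
            (int(r["position"]), r["ref"], r["alt"])
            for _, r in paper_fixture.unknown.iterrows()
        }
        # the two lists share exactly the two double-damaging unknown variants
        assert conc_keys & unk_keys == {(9500, "C", "A"), (9577, "T", "C")}
        assert len(conc_keys | unk_keys) == 57

    def test_written_bundle_is_stable(self, tmp_path):
        make_paper_fixture(tmp_path / "a")
        make_paper_fixture(tmp_path / "b")
        for f in (tmp_path / "a").iterdir():
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes()
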