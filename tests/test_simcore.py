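"""Unit and property tests for the invasion simulator."""

import numpy as np
import pytest
from scipy import stats as sps

from idroute.simcore import (
    ExtinctionError,
    IDVariant,
    Individual,
    Population,
    SimConfig,
    TEInsertion,
    VariantRegistry,
    init_population,
    is_active,
    make_gamete,
    migrate,
    population_fingerprint,
    run_single_invasion,
    run_stepping_stone,
    step_generation,
    transpose_into_gamete,
)

from conftest import small_config


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------


class TestInitPopulation:
    def test_empty(self, small_cfg, rng):
        pop = init_population(small_cfg, 0, rng)
        assert pop.n_copies == 0
        with pytest.raises(ValueError):
            population_fingerprint(pop, VariantRegistry(small_cfg.te_length))

    def test_each_insertion_on_one_haplotype(self, rng):
        cfg = SimConfig(n_fl_init=300, N=1000)
        pop = init_population(cfg, 300, rng)
        assert pop.n_copies == 300
        # every column carried exactly once: population frequency 1/2N
        counts = np.bincount(pop.e_col, minlength=len(pop.col_site))
        assert (counts == 1).all()
        assert len(np.unique(pop.col_site)) == 300
        assert (pop.col_allele == 0).all()

    def test_conservation_at_250(self, small_cfg, rng):
        pop = init_population(small_cfg, 250, rng)
        assert pop.n_copies == 250

    def test_too_many_sites_error(self, rng):
        cfg = small_config()
        with pytest.raises(ValueError):
            init_population(cfg, cfg.genome().total_bp + 1, rng)


# ---------------------------------------------------------------------------
# trap-model activity
# ---------------------------------------------------------------------------


class TestIsActive:
    def _genome(self):
        return small_config().genome()  # chromosomes 200kb, clusters last 20kb

    def test_single_fl_outside_cluster_active(self):
        ind = Individual([TEInsertion(0, 1000)], [])
        assert is_active(ind, self._genome())

    def test_only_ids_inactive(self):
        v = IDVariant(100, 900, 1)
        ind = Individual([TEInsertion(0, 1000, v)], [TEInsertion(1, 5000, v)])
        assert not is_active(ind, self._genome())

    def test_cluster_id_silences_despite_fl(self):
        v = IDVariant(100, 900, 1)
        hap0 = [TEInsertion(0, 1000), TEInsertion(0, 2000), TEInsertion(1, 3000)]
        hap1 = [TEInsertion(1, 190_000, v)]  # inside the terminal 20-kb cluster
        assert not is_active(Individual(hap0, hap1), self._genome())

    def test_cluster_fl_silences(self):
        ind = Individual([TEInsertion(0, 185_000)], [])
        assert not is_active(ind, self._genome())

    def test_matches_vectorized_engine(self, small_cfg, rng):
        cfg = small_config(c=0.05, generations=40)
        reg = VariantRegistry(cfg.te_length)
        pop = init_population(cfg, 60, rng)
        for _ in range(40):
            pop = step_generation(pop, cfg, rng, reg)
        mask = pop.active_mask()
        genome = pop.genome
        for i in range(cfg.N):
            assert mask[i] == is_active(pop.individual(i, reg), genome)


# ---------------------------------------------------------------------------
# meiosis
# ---------------------------------------------------------------------------


class TestMakeGamete:
    def test_no_recombination_copies_one_haplotype(self, rng):
        cfg = small_config(recombination_cm_mb=0.0)
        hap0 = [TEInsertion(0, 10), TEInsertion(0, 50_000)]
        hap1 = [TEInsertion(0, 99_000)]
        ind = Individual(hap0, hap1)
        for _ in range(20):
            g = make_gamete(ind, cfg, rng)
            assert g in (hap0, hap1)

    def test_homozygous_parent_gamete_identical(self, rng):
        cfg = small_config(recombination_cm_mb=10.0)
        hap = [TEInsertion(0, 10), TEInsertion(1, 50_000)]
        ind = Individual(list(hap), list(hap))
        for _ in range(20):
            assert make_gamete(ind, cfg, rng) == hap

    def test_crossover_count_matches_poisson_mean(self, rng):
        # 4 cM/Mb on a 1-Mb chromosome: 0.04 expected crossovers per meiosis.
        # Count recombinant (mosaic) gametes of a doubly heterozygous parent
        # carrying markers at the two chromosome ends; a single crossover
        # between them makes the gamete carry both or neither marker.
        cfg = SimConfig(chromosome_lengths=[1_000_000], cluster_lengths=1,
                        recombination_cm_mb=4.0, N=100, n_fl_init=0)
        a, b = TEInsertion(0, 1), TEInsertion(0, 1_000_000)
        ind = Individual([a], [b])
        n = 10_000
        recomb = 0
        for _ in range(n):
            g = make_gamete(ind, cfg, rng)
            if len(g) != 1:
                recomb += 1
        # P(odd # crossovers between the ends) ~ 0.04 * e^-0.04 ~ 0.0384
        expected = 0.04 * np.exp(-0.04)
        se = np.sqrt(expected * (1 - expected) / n)
        assert abs(recomb / n - expected) < 4 * se


class TestTransposeIntoGamete:
    def _parent(self, n_fl=10):
        return Individual([TEInsertion(0, 100 * (i + 1)) for i in range(n_fl)], [])

    def test_conversion_disabled_never_makes_ids(self, rng):
        cfg = small_config(c=0.0)
        for _ in range(50):
            out = transpose_into_gamete(self._parent(), [], cfg, rng)
            assert all(i.is_fl for i in out)

    def test_forced_conversion_makes_fresh_ids(self, rng):
        cfg = small_config(c=1.0)
        reg = VariantRegistry(cfg.te_length)
        seen = set()
        for _ in range(50):
            out = transpose_into_gamete(self._parent(), [], cfg, rng, reg)
            for ins in out:
                assert not ins.is_fl
                assert 1 <= ins.variant.start < ins.variant.end <= cfg.te_length
                assert ins.variant.vid not in seen
                seen.add(ins.variant.vid)

    def test_inactive_parent_gamete_unchanged(self, rng):
        cfg = small_config(c=0.5)
        v = IDVariant(5, 50, 1)
        parent = Individual([TEInsertion(0, 100, v)], [])  # no FL -> inactive
        gamete = [TEInsertion(1, 77)]
        assert transpose_into_gamete(parent, gamete, cfg, rng) == gamete

    def test_poisson_mean_u_n_over_2(self, rng):
        cfg = small_config(u=0.1)
        parent = self._parent(10)  # n = 10 -> mean 0.5 per gamete
        n = 10_000
        total = sum(len(transpose_into_gamete(parent, [], cfg, rng)) for _ in range(n))
        mean = total / n
        se = np.sqrt(0.5 / n)
        assert abs(mean - 0.5) < 4 * se

    def test_id_template_breakpoints_inherited(self, rng):
        cfg = small_config(u=5.0, c=1.0, fl_id=0.01)  # mobilize IDs nearly always
        v = IDVariant(100, 2000, 1)
        parent = Individual([TEInsertion(0, 500)], [TEInsertion(0, 900, v)])
        out = transpose_into_gamete(parent, [], cfg, rng)
        copies = [i for i in out if not i.is_fl and i.variant.vid == 1]
        assert copies, "expected at least one copy templated from the ID"
        assert all((c.variant.start, c.variant.end) == (100, 2000) for c in copies)


# ---------------------------------------------------------------------------
# generation step
# ---------------------------------------------------------------------------


class TestStepGeneration:
    def test_population_size_constant(self, rng):
        cfg = small_config(c=0.05)
        reg = VariantRegistry(cfg.te_length)
        pop = init_population(cfg, 60, rng)
        for _ in range(30):
            pop = step_generation(pop, cfg, rng, reg)
            assert pop.copy_numbers().shape == (cfg.N,)
            assert pop.e_hap.max(initial=0) < 2 * cfg.N

    def test_neutral_copy_number_conserved_in_expectation(self):
        # u=0, c=0, x=0: only drift; mean over replicates stays at the
        # initial count
        cfg = small_config(u=0.0)
        finals = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            reg = VariantRegistry(cfg.te_length)
            pop = init_population(cfg, 60, rng)
            for _ in range(50):
                pop = step_generation(pop, cfg, rng, reg)
            finals.append(pop.n_copies)
        se = np.std(finals, ddof=1) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - 60) < 3 * se + 1e-9

    def test_parent_usage_uniform_when_neutral(self, rng):
        from idroute.simcore import _draw_parents

        N = 50
        counts = np.zeros(N)
        for _ in range(100):
            pa, pb = _draw_parents(N, None, rng)
            counts += np.bincount(pa, minlength=N) + np.bincount(pb, minlength=N)
            assert not (pa == pb).any()
        chi2 = ((counts - counts.mean()) ** 2 / counts.mean()).sum()
        assert sps.chi2.sf(chi2, N - 1) > 0.01

    def test_fixed_cluster_insertion_silences_permanently(self, rng):
        # a cluster insertion fixed on every haplotype is inherited by all
        # offspring: the TE never transposes again
        cfg = small_config(c=0.5)
        genome = cfg.genome()
        N = cfg.N
        # column 0: FL inside the cluster, carried by all 2N haplotypes
        # (fixed); plus one segregating FL outside per individual
        sites = [genome.site_of(0, 185_000)]
        e_hap = list(range(2 * N))
        e_col = [0] * (2 * N)
        for i in range(N):
            sites.append(genome.site_of(1, 10 + i))
            e_hap.append(2 * i)
            e_col.append(1 + i)
        pop = Population.from_columns(
            N, genome, np.array(sites), np.zeros(len(sites), np.int32),
            np.array(e_hap), np.array(e_col))
        reg = VariantRegistry(cfg.te_length)
        for _ in range(10):
            pop = step_generation(pop, cfg, rng, reg)
            assert pop.active_mask().sum() == 0
            assert len(reg) == 0  # no conversion events ever happen

    def test_extinction_error(self, rng):
        cfg = small_config(x=1.0)  # any copy is lethal
        reg = VariantRegistry(cfg.te_length)
        # every individual carries one copy by construction
        genome = cfg.genome()
        sites = np.arange(2 * cfg.N)
        pop = Population.from_columns(
            cfg.N, genome, sites, np.zeros(len(sites), np.int32),
            np.arange(2 * cfg.N), np.arange(2 * cfg.N))
        with pytest.raises(ExtinctionError):
            step_generation(pop, cfg, rng, reg)


# ---------------------------------------------------------------------------
# migration
# ---------------------------------------------------------------------------


class TestMigrate:
    def test_zero_migrants_noop(self, small_cfg, rng):
        genome = small_cfg.genome()
        src = init_population(small_cfg, 50, rng, genome)
        dst = Population.empty(small_cfg.N, genome)
        s2, d2 = migrate(src, dst, 0, rng)
        assert d2.n_copies == 0 and s2 is src

    def test_full_replacement_copies_source(self, small_cfg, rng):
        genome = small_cfg.genome()
        src = init_population(small_cfg, 50, rng, genome)
        dst = Population.empty(small_cfg.N, genome)
        _, d2 = migrate(src, dst, small_cfg.N, rng)
        assert d2.n_copies == src.n_copies
        assert sorted(d2.col_site[d2.e_col]) == sorted(src.col_site[src.e_col])
        # per-individual copy multiset preserved under permutation
        assert sorted(d2.copy_numbers()) == sorted(src.copy_numbers())

    def test_invaded_to_naive_triggers_copies(self, small_cfg, rng):
        genome = small_cfg.genome()
        src = init_population(small_cfg, 150, rng, genome)
        dst = Population.empty(small_cfg.N, genome)
        _, d2 = migrate(src, dst, 100, rng)
        assert d2.n_copies > 0
        assert len(d2.e_hap) == len(d2.e_col)

    def test_too_many_migrants(self, small_cfg, rng):
        genome = small_cfg.genome()
        src = init_population(small_cfg, 10, rng, genome)
        with pytest.raises(ValueError):
            migrate(src, Population.empty(small_cfg.N, genome), small_cfg.N + 1, rng)

    def test_source_unchanged_and_sizes_kept(self, small_cfg, rng):
        genome = small_cfg.genome()
        src = init_population(small_cfg, 80, rng, genome)
        before = src.n_copies
        _, d2 = migrate(src, Population.empty(small_cfg.N, genome), 30, rng)
        assert src.n_copies == before
        assert d2.copy_numbers().shape == (small_cfg.N,)


# ---------------------------------------------------------------------------
# fingerprints of simulated demes
# ---------------------------------------------------------------------------


class TestPopulationFingerprint:
    def _pop_with(self, counts, rng):
        """counts: dict allele_id -> copy count (0 = FL)."""
        cfg = small_config()
        genome = cfg.genome()
        reg = VariantRegistry(cfg.te_length)
        for _ in range(max(counts) if counts else 0):
            reg.new_batch(1, rng)
        sites, alleles, e_hap, e_col = [], [], [], []
        col = 0
        hap = 0
        for a, k in counts.items():
            sites.append(1000 + 97 * col)
            alleles.append(a)
            for _ in range(k):
                e_hap.append(hap % (2 * cfg.N))
                e_col.append(col)
                hap += 1
            col += 1
        pop = Population.from_columns(cfg.N, genome, np.array(sites),
                                      np.array(alleles, np.int32),
                                      np.array(e_hap), np.array(e_col))
        return pop, reg

    def test_single_id_frequency(self, rng):
        pop, reg = self._pop_with({0: 75, 1: 25}, rng)
        fp = population_fingerprint(pop, reg)
        assert len(fp.entries) == 1
        assert fp.entries[0].frequency == pytest.approx(0.25)
        assert 1 - fp.total_id_frequency() == pytest.approx(0.75)

    def test_all_fl(self, rng):
        pop, reg = self._pop_with({0: 40}, rng)
        fp = population_fingerprint(pop, reg)
        assert fp.entries == []

    def test_three_ids(self, rng):
        pop, reg = self._pop_with({0: 70, 1: 10, 2: 10, 3: 10}, rng)
        fp = population_fingerprint(pop, reg)
        assert sorted(e.frequency for e in fp.entries) == pytest.approx([0.1] * 3)
        assert 1 - fp.total_id_frequency() == pytest.approx(0.7)


# ---------------------------------------------------------------------------
# whole runs
# ---------------------------------------------------------------------------


class TestRuns:
    def test_no_conversion_no_ids(self):
        cfg = small_config(c=0.0, generations=100, seed=7)
        rec = run_single_invasion(cfg)
        assert (rec.fraction_id == 0).all()
        assert (rec.n_variants == 0).all()

    def test_determinism_bit_identical(self):
        cfg = small_config(c=0.05, generations=60, seed=5)
        r1 = run_single_invasion(cfg)
        r2 = run_single_invasion(cfg)
        assert (r1.copy_number == r2.copy_number).all()
        assert (r1.fraction_id == r2.fraction_id).all()
        assert (r1.cluster_insertions == r2.cluster_insertions).all()

    def test_invasion_grows_then_plateaus(self):
        rec = run_single_invasion(small_config(generations=150, seed=2))
        assert rec.copy_number[-1] > 5 * rec.copy_number[0]
        late = rec.copy_number[-30:]
        early_growth = rec.copy_number[40] / max(rec.copy_number[5], 1e-9)
        late_growth = late[-1] / late[0]
        assert late_growth < early_growth

    def test_abundance_insensitive_to_conversion(self):
        # conversion only relabels copies as IDs; the copy-number
        # distribution must be indistinguishable between c=0 and c=0.05
        finals0, finals5 = [], []
        for seed in range(25):
            finals0.append(run_single_invasion(
                small_config(c=0.0, generations=120, seed=seed)).copy_number[-1])
            finals5.append(run_single_invasion(
                small_config(c=0.05, generations=120, seed=1000 + seed)).copy_number[-1])
        assert sps.ks_2samp(finals0, finals5).pvalue > 0.01

    def test_plateau_fraction_monotone_in_c(self):
        means = []
        for c in (0.0, 0.01, 0.05):
            vals = [run_single_invasion(
                small_config(c=c, generations=150, seed=s)).fraction_id[-30:].mean()
                for s in range(5)]
            means.append(np.mean(vals))
        assert means[0] == 0.0
        assert means[0] <= means[1] <= means[2]

    def test_fraction_id_flat_after_silencing(self):
        # once the TE is silenced the ID fraction shows no systematic trend:
        # single replicates drift, but the replicate-mean slope is zero
        slopes = []
        for seed in range(10):
            rec = run_single_invasion(small_config(c=0.05, generations=300, seed=seed))
            tail = rec.fraction_id[-100:]
            slopes.append(sps.linregress(np.arange(len(tail)), tail).slope)
        assert sps.ttest_1samp(slopes, 0.0).pvalue > 0.01

    def test_stepping_stone_no_migration_means_no_spread(self):
        cfg = small_config(n_populations=2, migration_size=0,
                           migration_interval=50, generations=120, seed=4)
        res = run_stepping_stone(cfg)
        assert res.records[1].copy_number[-1] == 0

    def test_stepping_stone_id_fraction_increases_along_chain(self, stepping_runs):
        # successively invaded demes accumulate a larger ID fraction: rank
        # correlation of deme order vs final ID fraction, pooled over the
        # full-protocol replicates
        orders, fracs = [], []
        for res in stepping_runs:
            for r in res.records:
                if r.copy_number[-1] > 0:
                    orders.append(r.population)
                    fracs.append(r.fraction_id[-1])
        rho, p = sps.spearmanr(orders, fracs)
        assert rho > 0 and p < 0.01

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            run_stepping_stone(small_config(n_populations=5, migration_interval=100,
                                            generations=150))
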