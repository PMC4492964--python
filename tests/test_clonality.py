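import itertools

import numpy as np
import pytest

from msatpop.clonality import (
    IncomparablePairError,
    MLLPartition,
    assign_mlls,
    clonality_index,
    collapse_to_mlls,
    flag_single_locus_variants,
    genotype_mismatch,
)
from msatpop.genotype import apply_locus_qc
from msatpop.simulate import SimConfig, simulate_dataset

from conftest import build_matrix, random_matrix


def brute_force_partition(matrix, max_mismatch=1, min_compared=5):
    """Oracle: BFS over the explicit pairwise link graph."""
    ids = matrix.sample_ids
    samples = {s.colony_id: s for s in matrix.samples}
    adj = {sid: set() for sid in ids}
    for a, b in itertools.combinations(ids, 2):
        d = genotype_mismatch(samples[a], samples[b])
        if d.n_compared >= min_compared and d.n_mismatch <= max_mismatch:
            adj[a].add(b)
            adj[b].add(a)
    seen = set()
    groups = []
    for sid in ids:
        if sid in seen:
            continue
        stack = [sid]
        comp = set()
        while stack:
            x = stack.pop()
            if x in comp:
                continue
            comp.add(x)
            stack.extend(adj[x] - comp)
        seen |= comp
        groups.append(frozenset(comp))
    return set(groups)


def as_groups(partition):
    return {frozenset(m) for m in partition.members().values()}


class TestGenotypeMismatch:
    def test_identical(self):
        m = random_matrix(0, n_samples=2, n_loci=27, p_missing=0)
        d = genotype_mismatch(m.samples[0], m.samples[1], loci=m.locus_ids)
        assert d.n_compared == 27

    def test_single_locus_difference(self):
        m = random_matrix(1, n_samples=1, n_loci=27, p_missing=0)
        a = m.samples[0]
        geno = dict(a.genotypes)
        x, y = geno["L7"]
        geno["L7"] = (x + 3, y + 3)
        b = build_matrix({"copy": list(geno.values())}, locus_ids=list(geno)).samples[0]
        d = genotype_mismatch(a, b)
        assert (d.n_compared, d.n_mismatch) == (27, 1)

    def test_missing_excluded(self):
        m = random_matrix(2, n_samples=2, n_loci=27, p_missing=0)
        a, b = m.samples
        for lid in ("L1", "L2", "L3"):
            a.genotypes[lid] = (0, 0)
        d = genotype_mismatch(a, b)
        assert d.n_compared == 24

    def test_incomparable_pair(self):
        m = build_matrix(
            {"a": [(100, 100), (0, 0)], "b": [(0, 0), (104, 104)]}
        )
        with pytest.raises(IncomparablePairError):
            genotype_mismatch(m.samples[0], m.samples[1])


class TestAssignMLLs:
    def test_all_distinct(self):
        m, _ = simulate_dataset(
            SimConfig(samples_per_pop=(12, 8), genets_per_pop=(12, 8), seed=5)
        )
        part = assign_mlls(m)
        assert part.n_mll == part.n == 20

    def test_planted_genets_recovered(self):
        cfg = SimConfig(
            n_loci=27,
            genets_per_pop=(10, 7),
            samples_per_pop=(53, 44),
            p_somatic=0.02,
            seed=17,
        )
        m, truth = simulate_dataset(cfg)
        sub = m.subset(mito_type="mt-L")
        part = assign_mlls(sub)
        assert part.n_mll == 10
        got = as_groups(part)
        want = {}
        for sid in sub.sample_ids:
            want.setdefault(truth.genet_of_sample[sid], set()).add(sid)
        assert got == {frozenset(v) for v in want.values()}

    @pytest.mark.parametrize("seed", range(12))
    def test_oracle_equivalence_small(self, seed):
        m = random_matrix(seed, n_samples=12, n_loci=8, n_alleles=3, p_missing=0.05)
        part = assign_mlls(m, min_compared=3)
        assert as_groups(part) == brute_force_partition(m, min_compared=3)

    def test_order_invariance(self):
        m, _ = simulate_dataset(
            SimConfig(n_pops=1, genets_per_pop=(4,), samples_per_pop=(15,),
                      p_somatic=0.1, seed=8)
        )
        part1 = as_groups(assign_mlls(m))
        rng = np.random.default_rng(0)
        order = rng.permutation(m.n_samples)
        from msatpop.genotype import GenotypeMatrix

        shuffled = GenotypeMatrix(
            loci=list(m.loci), samples=[m.samples[i] for i in order]
        )
        assert as_groups(assign_mlls(shuffled)) == part1

    def test_zero_mismatch_refines(self):
        m, _ = simulate_dataset(
            SimConfig(n_pops=1, genets_per_pop=(5,), samples_per_pop=(20,),
                      p_somatic=0.3, seed=13)
        )
        exact = assign_mlls(m, max_mismatch=0)
        loose = assign_mlls(m, max_mismatch=1)
        assert loose.n_mll <= exact.n_mll
        # max_mismatch=0 groups exactly the identical multilocus genotypes
        sig = {}
        for s in m.samples:
            key = tuple(sorted(s.genotypes.items()))
            sig.setdefault(key, set()).add(s.colony_id)
        assert as_groups(exact) == {frozenset(v) for v in sig.values()}

    def test_incomparable_error_lists_pair(self):
        m = build_matrix(
            {
                "a": [(100, 100), (0, 0), (101, 101), (0, 0), (100, 103)],
                "b": [(0, 0), (104, 104), (0, 0), (100, 100), (0, 0)],
            }
        )
        with pytest.raises(IncomparablePairError, match="'a' and 'b'"):
            assign_mlls(m, min_compared=1)

    def test_clean_recovery_rate(self):
        # no noise, 11 loci, >= 6 alleles: exact genet recovery nearly always
        hits = 0
        n_rep = 200
        for r in range(n_rep):
            cfg = SimConfig(
                n_pops=1,
                n_loci=11,
                alleles_per_locus=6,
                genets_per_pop=(8,),
                samples_per_pop=(16,),
                seed=50_000 + r,
            )
            m, truth = simulate_dataset(cfg)
            part = assign_mlls(m)
            want = {}
            for sid in m.sample_ids:
                want.setdefault(truth.genet_of_sample[sid], set()).add(sid)
            if as_groups(part) == {frozenset(v) for v in want.values()}:
                hits += 1
        assert hits / n_rep >= 0.99


class TestClonalityIndex:
    @pytest.mark.parametrize(
        "n_mll,n,expected", [(10, 53, 0.189), (7, 44, 0.159)]
    )
    def test_study_values(self, n_mll, n, expected):
        part = MLLPartition(
            assignment={
                f"c{i}": f"MLL{min(i, n_mll)}" for i in range(1, n + 1)
            }
        )
        assert (part.n_mll, part.n) == (n_mll, n)
        assert round(clonality_index(part), 3) == expected

    def test_all_unique(self):
        part = MLLPartition(assignment={f"c{i}": f"M{i}" for i in range(9)})
        assert clonality_index(part) == 1.0


class TestFlagSingleLocusVariants:
    def _three_ramets_one_deviant(self):
        base = [(100, 103), (200, 200), (300, 306), (400, 400), (500, 503),
                (150, 150), (250, 253)]
        rows = {"r1": list(base), "r2": list(base), "r3": list(base)}
        rows["r3"][4] = (500, 506)  # deviant at L5
        return build_matrix(rows)

    def test_names_deviant_sample(self):
        m = self._three_ramets_one_deviant()
        part = assign_mlls(m)
        assert part.n_mll == 1
        flags = flag_single_locus_variants(m, part, mode="zero_allele")
        assert [(f.locus_id, f.sample_id, f.action) for f in flags] == [
            ("L5", "r3", "zero_allele")
        ]

    def test_drop_mode_flags_locus_only(self):
        m = self._three_ramets_one_deviant()
        part = assign_mlls(m)
        flags = flag_single_locus_variants(m, part, mode="drop_locus")
        assert [(f.locus_id, f.sample_id, f.action) for f in flags] == [
            ("L5", None, "drop_locus")
        ]

    def test_clean_clonal_data_no_flags(self):
        base = [(100, 103), (200, 200), (300, 306), (400, 400), (500, 503)]
        m = build_matrix({f"r{i}": list(base) for i in range(1, 5)})
        part = assign_mlls(m)
        assert flag_single_locus_variants(m, part) == []

    def test_planted_mutations_flagged_exactly(self):
        for r in range(25):
            cfg = SimConfig(
                n_pops=1,
                n_loci=11,
                genets_per_pop=(6,),
                samples_per_pop=(24,),
                p_somatic=0.15,
                seed=900 + r,
            )
            m, truth = simulate_dataset(cfg)
            part = assign_mlls(m)
            flags = flag_single_locus_variants(m, part, mode="zero_allele")
            got = {(f.sample_id, f.locus_id) for f in flags}
            want = {(sid, lid) for sid, lid, _, _ in truth.mutations}
            assert got == want

    def test_end_to_end_drop_planted_locus(self):
        cfg = SimConfig(
            n_pops=1,
            n_loci=11,
            genets_per_pop=(5,),
            samples_per_pop=(20,),
            p_somatic=0.0,
            seed=77,
        )
        m, truth = simulate_dataset(cfg)
        # plant exactly one somatic change by hand at L04 on a known ramet
        genet_of = truth.genet_of_sample
        mates = {}
        for sid, g in genet_of.items():
            mates.setdefault(g, []).append(sid)
        target_genet = next(g for g, ms in mates.items() if len(ms) >= 2)
        victim = mates[target_genet][1]
        vict = next(s for s in m.samples if s.colony_id == victim)
        a, b = vict.genotypes["L04"]
        vict.genotypes["L04"] = (a, b + 4)
        part = assign_mlls(m)
        flags = flag_single_locus_variants(m, part, mode="drop_locus")
        assert [f.locus_id for f in flags] == ["L04"]
        cleaned = apply_locus_qc(m, flags)
        assert cleaned.n_loci == 10


class TestCollapse:
    def test_first_representative_kept(self):
        m, _ = simulate_dataset(
            SimConfig(n_pops=1, genets_per_pop=(4,), samples_per_pop=(12,), seed=2)
        )
        part = assign_mlls(m)
        coll = collapse_to_mlls(m, part)
        assert coll.n_samples == part.n_mll
        firsts = set()
        expect = []
        for s in m.samples:
            mid = part.assignment[s.colony_id]
            if mid not in firsts:
                firsts.add(mid)
                expect.append(s.colony_id)
        assert coll.sample_ids == expect
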