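import numpy as np
import pytest

from caprilact.errors import DegenerateDataError, ValidationError
from caprilact.haplotypes import (
    CASEIN_BLOCKS,
    HaplotypeAssignment,
    group_by_haplotype,
    haplotype_key,
    heterozygosity,
    ld_pair,
    maf,
    parse_haplotypes,
    snp_calls,
    write_haplotypes,
)
from caprilact.simulate import default_haplotype_inventory


def _hap(tokens_by_block=None, csn1s1=None):
    """A full valid haplotype dict, optionally overriding CSN1S1."""
    _, seqs = default_haplotype_inventory(2, seed=3)
    base = dict(next(iter(seqs.values())))
    if csn1s1 is not None:
        base["CSN1S1"] = tuple(csn1s1)
    if tokens_by_block:
        base.update(tokens_by_block)
    return base


class TestParsing:
    def test_round_trip(self, tmp_path, small_herd):
        path = tmp_path / "haps.csv"
        write_haplotypes(small_herd.assignments, path)
        back = parse_haplotypes(path)
        assert back == small_herd.assignments

    def test_eighteen_tokens_accepted(self):
        a = HaplotypeAssignment("G1", _hap(csn1s1="AAGGAATTAAAAGGCCAA"), _hap())
        assert len(a.hap1["CSN1S1"]) == 18

    def test_token_count_mismatch_names_animal_and_block(self, tmp_path):
        a = HaplotypeAssignment("G7", _hap(csn1s1="AAGGAATTAAAAGGCCA"), _hap())
        path = tmp_path / "haps.csv"
        write_haplotypes([a], path)
        with pytest.raises(ValidationError, match=r"G7.*CSN1S1.*17"):
            parse_haplotypes(path)

    def test_indel_tokens_parse_as_single_alleles(self, tmp_path):
        h = _hap({"CSN3": ("T", ".-", "AATC", "C")})
        a = HaplotypeAssignment("G1", h, _hap())
        path = tmp_path / "haps.csv"
        write_haplotypes([a], path)
        (back,) = parse_haplotypes(path)
        assert back.hap1["CSN3"] == ("T", ".-", "AATC", "C")


class TestMaf:
    def test_monomorphic(self):
        r = maf(["A"] * 12)
        assert r.maf == 0.0 and r.monomorphic and not r.rare

    def test_direct_count(self):
        r = maf(["A"] * 30 + ["G"] * 10)
        assert r.maf == pytest.approx(0.25)
        assert r.minor_allele == "G" and not r.rare

    def test_rare_threshold(self):
        r = maf(["A"] * 39 + ["G"])
        assert r.maf == pytest.approx(1 / 40) and r.rare
        assert not maf(["A"] * 38 + ["G"] * 2).rare  # 0.05 itself is not rare

    def test_label_swap_invariance(self):
        assert maf(["A"] * 30 + ["G"] * 10).maf == maf(["G"] * 30 + ["A"] * 10).maf

    def test_triallelic_rejected(self):
        with pytest.raises(ValidationError, match="two alleles"):
            maf(["A", "C", "G"])


class TestHeterozygosity:
    def test_extremes(self):
        hom = HaplotypeAssignment("G1", _hap(), _hap())
        assert heterozygosity([hom], "CSN1S1", 0) == 0.0
        h2 = _hap()
        other = "T" if h2["CSN1S1"][0] != "T" else "A"
        h2["CSN1S1"] = (other,) + tuple(h2["CSN1S1"][1:])
        het = HaplotypeAssignment("G2", _hap(), h2)
        assert heterozygosity([het], "CSN1S1", 0) == 1.0

    def test_hardy_weinberg_expectation(self, rng):
        # p = 0.5 biallelic SNP: expect 2pq = 0.5 heterozygotes
        n = 4000
        base = _hap()
        animals = []
        for i in range(n):
            phases = []
            for _ in range(2):
                h = dict(base)
                tok = "A" if rng.random() < 0.5 else "G"
                h["CSN2"] = (tok,) + base["CSN2"][1:]
                phases.append(h)
            animals.append(HaplotypeAssignment(f"G{i}", *phases))
        frac = heterozygosity(animals, "CSN2", 0)
        assert frac == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(n))


class TestLd:
    def test_complete_ld(self):
        a = ["A"] * 40 + ["G"] * 60
        b = ["T"] * 40 + ["C"] * 60
        dprime, r2 = ld_pair(a, b)
        assert dprime == pytest.approx(1.0) and r2 == pytest.approx(1.0)

    def test_contingency_table_oracle(self):
        # AB:40, Ab:10, aB:10, ab:40
        a = ["A"] * 50 + ["a"] * 50
        b = ["B"] * 40 + ["b"] * 10 + ["B"] * 10 + ["b"] * 40
        dprime, r2 = ld_pair(a, b)
        p_a, p_b, p_ab = 0.5, 0.5, 0.4
        d = p_ab - p_a * p_b
        dmax = min(p_a * (1 - p_b), (1 - p_a) * p_b)
        assert dprime == pytest.approx(abs(d / dmax))
        assert r2 == pytest.approx(d**2 / (p_a * (1 - p_a) * p_b * (1 - p_b)))

    def test_independent_phases_near_zero(self, rng):
        n = 20000
        a = np.where(rng.random(n) < 0.4, "A", "G").tolist()
        b = np.where(rng.random(n) < 0.6, "T", "C").tolist()
        dprime, r2 = ld_pair(a, b)
        assert r2 < 0.001

    def test_bounds_and_r2_one_implies_dprime_one(self, rng):
        for _ in range(20):
            n = 200
            a = np.where(rng.random(n) < rng.uniform(0.2, 0.8), "A", "G")
            b = np.where(rng.random(n) < rng.uniform(0.2, 0.8), "T", "C")
            if len(set(a)) < 2 or len(set(b)) < 2:
                continue
            dprime, r2 = ld_pair(a.tolist(), b.tolist())
            assert 0.0 <= dprime <= 1.0 + 1e-12
            assert 0.0 <= r2 <= 1.0 + 1e-12
            assert r2 <= dprime**2 + 1e-9  # r2 = 1 forces |D'| = 1

    def test_monomorphic_signaled(self):
        with pytest.raises(DegenerateDataError):
            ld_pair(["A"] * 10, ["T"] * 5 + ["C"] * 5)


class TestGrouping:
    def test_study_scale_ratio(self):
        # 159 animals cycling over an inventory of 86 distinct haplotypes
        _, seqs = default_haplotype_inventory(86, seed=5)
        haps = list(seqs.values())
        animals = [
            HaplotypeAssignment(
                f"G{i:03d}", dict(haps[(2 * i) % 86]), dict(haps[(2 * i + 1) % 86])
            )
            for i in range(159)
        ]
        g = group_by_haplotype(animals)
        assert g.n_animals == 159 and g.n_haplotypes == 86
        assert round(g.animals_per_haplotype, 2) == 1.85

    def test_identical_homozygotes_one_group(self):
        h = _hap()
        animals = [HaplotypeAssignment(f"G{i}", dict(h), dict(h)) for i in range(5)]
        g = group_by_haplotype(animals)
        assert len(g.groups) == 1 and g.n_haplotypes == 1

    def test_recovers_generator_inventory(self, small_herd):
        realized = set()
        for a in small_herd.assignments:
            realized.add(haplotype_key(a.hap1))
            realized.add(haplotype_key(a.hap2))
        g = group_by_haplotype(small_herd.assignments)
        assert set(g.groups) == realized
        assert g.n_haplotypes == len(realized)

    def test_membership_rule(self, small_herd):
        g = group_by_haplotype(small_herd.assignments)
        counts = {}
        for members in g.groups.values():
            for a in members:
                counts[a] = counts.get(a, 0) + 1
        assert set(counts) == {a.animal_id for a in small_herd.assignments}
        assert all(1 <= c <= 2 for c in counts.values())

    def test_homozygous_only_disjoint(self, small_herd):
        g = group_by_haplotype(small_herd.assignments, homozygous_only=True)
        seen = set()
        for members in g.groups.values():
            assert not (set(members) & seen)
            seen.update(members)

    def test_snp_calls_shape(self, small_herd):
        calls = snp_calls(small_herd.assignments, "CSN1S1", 0)
        assert len(calls) == 2 * len(small_herd.assignments)


class TestSnpMatrixAndLdTable:
    def test_matrix_layout_matches_assignments(self, small_herd):
        from caprilact.haplotypes import SnpMatrix

        m = SnpMatrix.from_assignments(small_herd.assignments)
        n = len(small_herd.assignments)
        assert m.phase1.shape == (n, 48) and m.phase2.shape == (n, 48)
        assert m.snp_ids[0] == "CSN1S1_01" and m.snp_ids[-1] == "CSN3_04"
        # first CSN1S2 column sits right after the 18 CSN1S1 columns
        a0 = small_herd.assignments[0]
        assert m.phase1[0, 18] == a0.hap1["CSN1S2"][0]
        # phases are stacked rather than interleaved; same pooled calls
        assert sorted(m.calls(0)) == sorted(
            snp_calls(small_herd.assignments, "CSN1S1", 0)
        )

    def test_ld_table_consistent_with_ld_pair(self, small_herd):
        from caprilact.haplotypes import ld_table

        table = ld_table(small_herd.assignments)
        assert {"snp_i", "snp_j", "dprime", "r2"} <= set(table.columns)
        assert ((table["r2"] >= 0) & (table["r2"] <= 1 + 1e-12)).all()
        assert ((table["dprime"] >= 0) & (table["dprime"] <= 1 + 1e-12)).all()
        row = table.iloc[0]
        snp_index = {s: i for b in CASEIN_BLOCKS for i, s in enumerate(b.snp_ids)}
        blk = {s: b.name for b in CASEIN_BLOCKS for s in b.snp_ids}
        ci = snp_calls(small_herd.assignments, blk[row["snp_i"]], snp_index[row["snp_i"]])
        cj = snp_calls(small_herd.assignments, blk[row["snp_j"]], snp_index[row["snp_j"]])
        dprime, r2 = ld_pair(ci, cj)
        assert row["dprime"] == pytest.approx(dprime)
        assert row["r2"] == pytest.approx(r2)
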