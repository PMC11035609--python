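"""Score-construction contracts: QC filters, greedy clumping vs a
brute-force oracle, region/catalog exclusions, scoring identities."""
import numpy as np
import pandas as pd
import pytest

from wbcpgs import SimConfig, pgs, synthdata
from wbcpgs.errors import (DegenerateInputError, InsufficientDataError,
                           LookupFailure, ValidationError)
from conftest import make_toy_panel


def _summary_row(vid="v0", chrom="1", pos=100, ea="A", oa="G", beta=0.1,
                 p=1e-7, eaf=0.3, info=0.9):
    return {"variant_id": vid, "chrom": chrom, "pos": pos,
            "effect_allele": ea, "other_allele": oa, "beta": beta,
            "p": p, "eaf": eaf, "info": info}


class TestQcFilter:
    @pytest.mark.parametrize("row,kept,reason", [
        (_summary_row(p=1e-6, eaf=0.05, info=0.9, ea="A", oa="G"), True, None),
        (_summary_row(ea="A", oa="T"), False, "palindromic"),
        (_summary_row(ea="C", oa="G"), False, "palindromic"),
        (_summary_row(eaf=0.995), False, "maf"),
        (_summary_row(p=5e-6), False, "p"),
        (_summary_row(info=0.69), False, "info"),
        (_summary_row(info=0.7), True, None),
    ])
    def test_single_record_rules(self, row, kept, reason):
        table = pd.DataFrame([row])
        retained, log = pgs.qc_filter(table)
        assert (len(retained) == 1) == kept
        if not kept:
            assert log["detail"].iloc[0] == reason

    def test_malformed_alleles_listed(self):
        table = pd.DataFrame([_summary_row(vid="bad", ea="N")])
        with pytest.raises(ValidationError) as err:
            pgs.qc_filter(table)
        assert "bad" in err.value.rows

    def test_empty_table_rejected(self):
        with pytest.raises(InsufficientDataError):
            pgs.qc_filter(pd.DataFrame(columns=list(_summary_row())))


def clump_oracle(candidates: pd.DataFrame, dosages: np.ndarray,
                 r2_max: float) -> list:
    """Independent greedy clump: explicit pairwise correlations, pure
    python bookkeeping."""
    order = sorted(range(len(candidates)),
                   key=lambda i: (candidates.iloc[i]["p"],
                                  candidates.iloc[i]["variant_id"]))
    kept, removed = [], set()
    for i in order:
        if i in removed:
            continue
        kept.append(candidates.iloc[i]["variant_id"])
        for j in order:
            if j == i or j in removed:
                continue
            xi, xj = dosages[:, i].astype(float), dosages[:, j].astype(float)
            if xi.std() == 0 or xj.std() == 0:
                r2 = 0.0
            else:
                r2 = np.corrcoef(xi, xj)[0, 1] ** 2
            if r2 >= r2_max:
                removed.add(j)
        removed.add(i)
    return kept


class TestLdClump:
    def test_single_candidate_retained(self, toy_panel):
        cand = pd.DataFrame([_summary_row(vid="v0")])
        kept, _ = pgs.ld_clump(cand, toy_panel)
        assert list(kept["variant_id"]) == ["v0"]

    def test_perfect_ld_keeps_smaller_p(self):
        col = np.array([0, 1, 2, 1, 0, 2, 1, 1, 0, 2], dtype=np.int8)
        panel = make_toy_panel(np.column_stack([col, col]))
        cand = pd.DataFrame([_summary_row(vid="v0", p=1e-8),
                             _summary_row(vid="v1", p=1e-7)])
        kept, log = pgs.ld_clump(cand, panel, r2_max=0.01)
        assert list(kept["variant_id"]) == ["v0"]
        assert log["step"].tolist() == ["clump"] and "v0" in log["detail"].iloc[0]

    def test_toy_fixture_matches_bruteforce_oracle(self, toy_panel):
        rng = np.random.default_rng(0)
        cand = pd.DataFrame([_summary_row(vid=f"v{j}", p=float(rng.uniform()))
                             for j in range(6)])
        kept, _ = pgs.ld_clump(cand, toy_panel, r2_max=0.2)
        oracle = clump_oracle(cand, toy_panel.dosages, 0.2)
        assert sorted(kept["variant_id"]) == sorted(oracle)

    def test_retained_pairs_below_threshold(self, small_summary, small_panel):
        filtered, _ = pgs.qc_filter(small_summary)
        kept, _ = pgs.ld_clump(filtered, small_panel, r2_max=0.01)
        D = small_panel.dosage_matrix(kept["variant_id"])
        r2 = np.corrcoef(D.T) ** 2
        np.fill_diagonal(r2, 0.0)
        assert np.nanmax(r2) < 0.01

    def test_absent_candidate_raises(self, toy_panel):
        cand = pd.DataFrame([_summary_row(vid="missing")])
        with pytest.raises(LookupFailure, match="missing"):
            pgs.ld_clump(cand, toy_panel)


class TestRegionExclusion:
    @pytest.mark.parametrize("chrom,pos,excluded", [
        ("6", 30_000_000, True),
        ("6", 25_499_999, False),
        ("6", 25_500_000, True),
        ("6", 33_500_000, True),
        ("6", 33_500_001, False),
        ("7", 30_000_000, False),
    ])
    def test_mhc_boundaries_inclusive(self, chrom, pos, excluded):
        table = pd.DataFrame([_summary_row(chrom=chrom, pos=pos)])
        kept, log = pgs.exclude_region(table, pgs.MHC_REGION)
        assert (len(kept) == 0) == excluded

    def test_parse_roundtrip(self):
        r = pgs.GenomicRegion.parse("6:25500000-33500000")
        assert r == pgs.MHC_REGION


class TestCatalogLd:
    def _setup(self, r):
        rng = np.random.default_rng(1)
        base = rng.integers(0, 3, size=2000).astype(float)
        noise = rng.integers(0, 3, size=2000).astype(float)
        mixed = np.where(rng.random(2000) < r, base, noise)
        panel = make_toy_panel(np.column_stack([base, mixed]).astype(np.int8))
        cand = pd.DataFrame([_summary_row(vid="v1")])
        return panel, cand

    def test_linked_candidate_excluded(self):
        panel, cand = self._setup(0.95)  # r2 ~ 0.9
        catalog = pd.DataFrame([{"variant_id": "v0", "phenotype": "lupus",
                                 "p": 1e-8}])
        kept, log, _ = pgs.exclude_catalog_ld(cand, catalog, panel)
        assert len(kept) == 0
        assert "v0" in log["detail"].iloc[0] and "lupus" in log["detail"].iloc[0]

    def test_weak_catalog_p_never_triggers(self):
        panel, cand = self._setup(0.95)
        catalog = pd.DataFrame([{"variant_id": "v0", "phenotype": "lupus",
                                 "p": 1e-6}])  # above 5e-7 cutoff
        kept, _, _ = pgs.exclude_catalog_ld(cand, catalog, panel)
        assert len(kept) == 1

    def test_boundary_r2_is_strict(self):
        # identical columns, r2 exactly 1 > 0.5 -> excluded; and a
        # constructed r2 = 0.5 boundary must be retained
        col = np.array([0.0, 1.0, 2.0, 1.0, 0.0, 2.0])
        # second column correlating at exactly sqrt(0.5) is awkward with
        # integer dosages; test the strictness on the r2_min parameter:
        panel = make_toy_panel(np.column_stack([col, col]).astype(np.int8))
        cand = pd.DataFrame([_summary_row(vid="v1")])
        catalog = pd.DataFrame([{"variant_id": "v0", "phenotype": "x",
                                 "p": 1e-9}])
        kept, _, _ = pgs.exclude_catalog_ld(cand, catalog, panel, r2_min=1.0)
        assert len(kept) == 1  # r2 == r2_min not strictly greater
        kept, _, _ = pgs.exclude_catalog_ld(cand, catalog, panel, r2_min=0.99)
        assert len(kept) == 0

    def test_absent_catalog_variant_warns_not_fails(self, toy_panel):
        cand = pd.DataFrame([_summary_row(vid="v1")])
        catalog = pd.DataFrame([{"variant_id": "nope", "phenotype": "x",
                                 "p": 1e-9}])
        kept, _, warnings = pgs.exclude_catalog_ld(cand, catalog, toy_panel)
        assert len(kept) == 1 and any("nope" in w for w in warnings)

    def test_ground_truth_tagged_variants_all_excluded(
            self, small_summary, small_panel, small_catalog):
        """Every candidate in LD r2>0.5 with a sub-5e-7 catalog variant is
        dropped; unlinked candidates are untouched by this step."""
        filtered, _ = pgs.qc_filter(small_summary)
        kept, log, _ = pgs.exclude_catalog_ld(filtered, small_catalog,
                                              small_panel)
        D_all = small_panel.dosage_matrix(filtered["variant_id"])
        D_cat = small_panel.dosage_matrix(small_catalog["variant_id"])
        R = np.corrcoef(D_all.T, D_cat.T)[:len(filtered), len(filtered):]
        linked = (R ** 2 > 0.5).any(axis=1)
        assert set(filtered.loc[linked, "variant_id"]) == set(log["variant_id"])
        assert set(kept["variant_id"]) == set(filtered.loc[~linked, "variant_id"])


class TestScoreStandardize:
    def test_hand_computed_score(self):
        panel = make_toy_panel(np.array([[2, 1]], dtype=np.int8))
        model = pgs.PgsModel(variants=pd.DataFrame({
            "variant_id": ["v0", "v1"], "effect_allele": ["A", "A"],
            "weight": [0.1, -0.2]}))
        assert pgs.score(panel, model)[0] == pytest.approx(0.0, abs=1e-15)

    def test_zero_dosage_and_linearity(self, toy_panel):
        model = pgs.PgsModel(variants=pd.DataFrame({
            "variant_id": ["v0", "v1"], "effect_allele": ["A", "A"],
            "weight": [0.3, 0.5]}))
        s1 = pgs.score(toy_panel, model)
        doubled = pgs.PgsModel(variants=model.variants.assign(
            weight=model.variants["weight"] * 2))
        assert np.allclose(pgs.score(toy_panel, doubled), 2 * s1)
        zero_panel = make_toy_panel(np.zeros((4, 6), dtype=np.int8))
        assert np.all(pgs.score(zero_panel, model) == 0.0)

    def test_orientation_flip_invariance(self, toy_panel):
        model = pgs.PgsModel(variants=pd.DataFrame({
            "variant_id": ["v0", "v1", "v2"],
            "effect_allele": ["A", "A", "A"],
            "weight": [0.3, -0.2, 0.15]}))
        z0, _, _ = pgs.standardize(pgs.score(toy_panel, model))
        flipped = model.variants.copy()
        flipped.loc[1, "effect_allele"] = "G"  # panel other allele
        flipped.loc[1, "weight"] = -flipped.loc[1, "weight"]
        z1, _, _ = pgs.standardize(pgs.score(
            toy_panel, pgs.PgsModel(variants=flipped)))
        assert np.allclose(z0, z1, atol=1e-10)

    def test_unknown_allele_raises(self, toy_panel):
        model = pgs.PgsModel(variants=pd.DataFrame({
            "variant_id": ["v0"], "effect_allele": ["C"], "weight": [1.0]}))
        with pytest.raises(LookupFailure):
            pgs.score(toy_panel, model)

    def test_standardize_contract(self):
        rng = np.random.default_rng(2)
        raw = rng.normal(size=500)
        z, m, s = pgs.standardize(raw)
        assert abs(z.mean()) < 1e-12 and abs(z.std(ddof=1) - 1) < 1e-12
        z2, _, _ = pgs.standardize(raw + 5.0)
        assert np.allclose(z, z2, atol=1e-10)
        new = np.array([1.23])
        z3, _, _ = pgs.standardize(new, reference=raw)
        assert z3[0] == pytest.approx((1.23 - m) / s, rel=1e-14)
        with pytest.raises(DegenerateInputError):
            pgs.standardize(np.ones(10))


class TestSensitivity:
    def _model(self):
        return pgs.PgsModel(variants=pd.DataFrame({
            "variant_id": ["a", "b"], "effect_allele": ["A", "A"],
            "weight": [0.1, 0.2]}))

    def test_threshold_behaviour(self):
        assoc = pd.DataFrame([{"variant_id": "a", "phenotype": "leukemia",
                               "p": 0.04}])
        dropped = pgs.sensitivity_exclude(self._model(), assoc, 0.05)
        assert dropped.variants["variant_id"].tolist() == ["b"]
        assert dropped.exclusions["step"].tolist() == ["sensitivity"]
        kept = pgs.sensitivity_exclude(self._model(), assoc, 0.001)
        assert kept.n_variants == 2
        unchanged = pgs.sensitivity_exclude(
            self._model(), assoc.iloc[0:0], 0.05)
        assert unchanged.n_variants == 2


class TestPipelineInvariants:
    def test_conservation_and_catalog_monotonicity(
            self, small_summary, small_panel, small_catalog):
        m_with = pgs.build_pgs_model(small_summary, small_panel,
                                     catalog=small_catalog)
        m_without = pgs.build_pgs_model(small_summary, small_panel)
        assert m_with.n_variants + len(m_with.exclusions) == len(small_summary)
        assert m_without.n_variants >= m_with.n_variants
        ids = pd.concat([m_with.variants["variant_id"],
                         m_with.exclusions["variant_id"]])
        assert sorted(ids) == sorted(small_summary["variant_id"])


class TestSelectThreshold:
    def _construct(self):
        """Only the genome-wide-significant variant drives the phenotype."""
        rng = np.random.default_rng(9)
        D = rng.integers(0, 3, size=(400, 4)).astype(np.int8)
        panel = make_toy_panel(D)
        summary = pd.DataFrame([
            _summary_row(vid="v0", pos=100, beta=1.0, p=1e-9),
            _summary_row(vid="v1", pos=1_000_000, beta=0.8, p=1e-7),
            _summary_row(vid="v2", pos=2_000_000, beta=-0.9, p=1e-7),
            _summary_row(vid="v3", pos=3_000_000, beta=0.7, p=2e-6),
        ])
        wbc = D[:, 0] * 1.0 + rng.normal(0, 0.5, size=400)
        persons = pd.DataFrame({
            "median_wbc": wbc,
            "age": rng.normal(50, 10, size=400),
            "sex": rng.integers(0, 2, size=400),
        })
        return summary, panel, persons

    def test_argmax_prefers_informative_threshold(self):
        summary, panel, persons = self._construct()
        chosen, table = pgs.select_threshold(summary, panel, persons,
                                             mhc=None)
        assert chosen == 5e-8
        assert len(table) == 3 and table["partial_r"].notna().all()

    def test_tie_breaks_to_most_stringent(self):
        summary, panel, persons = self._construct()
        # single variant passes every threshold -> identical correlations
        one = summary.iloc[[0]]
        chosen, table = pgs.select_threshold(one, panel, persons, mhc=None)
        assert chosen == 5e-8
        assert table["partial_r"].nunique() == 1

    def test_constant_covariates_reduce_to_plain_correlation(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=200), rng.normal(size=200)
        r_plain = np.corrcoef(x, y)[0, 1]
        r_partial = pgs.partial_correlation(x, y, np.ones((200, 2)))
        assert r_partial == pytest.approx(r_plain, abs=1e-12)

    def test_too_few_cases_rejected(self):
        summary, panel, persons = self._construct()
        with pytest.raises(InsufficientDataError):
            pgs.select_threshold(summary, panel, persons.head(2), mhc=None)
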