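"""Unit and property tests of the nine-gene p-EMT scoring chain."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from organquant import pemt
from organquant import synthdata as sd


def toy_table(pops: dict[str, float], gapdh: float = 20.0, n_rep: int = 1) -> pd.DataFrame:
    """Ct table where every panel gene of a population sits at the given Ct."""
    rows = []
    for pop, ct in pops.items():
        for rep in range(1, n_rep + 1):
            for g in pemt.DEFAULT_PANEL:
                rows.append((pop, g, rep, ct))
            rows.append((pop, pemt.REFERENCE_GENE, rep, gapdh))
    return pd.DataFrame(rows, columns=["population_id", "gene_id", "replicate", "ct"])


class TestDeltaCt:
    @pytest.mark.parametrize(
        "ct_gene,ct_gapdh,expected", [(25.0, 20.0, 5.0), (20.0, 20.0, 0.0), (18.0, 21.0, -3.0)]
    )
    def test_matches_reference_subtraction(self, ct_gene, ct_gapdh, expected):
        tab = toy_table({"A": ct_gene, "B": ct_gene + 1}, gapdh=ct_gapdh)
        dct = pemt.compute_delta_ct(tab)
        got = dct[(dct.population_id == "A")]["delta_ct"].unique()
        assert got == pytest.approx([expected])

    def test_missing_reference_names_block(self):
        tab = toy_table({"A": 25.0, "B": 26.0})
        tab = tab[~((tab.population_id == "B") & (tab.gene_id == pemt.REFERENCE_GENE))]
        with pytest.raises(ValueError, match="GAPDH.*B"):
            pemt.compute_delta_ct(tab)

    def test_missing_panel_gene_names_population(self):
        tab = toy_table({"A": 25.0, "B": 26.0})
        tab = tab[~((tab.population_id == "A") & (tab.gene_id == "PDPN"))]
        with pytest.raises(ValueError, match="'A'.*PDPN"):
            pemt.compute_delta_ct(tab)


class TestExpTransform:
    @pytest.mark.parametrize("dct,expected", [(0.0, 100.0), (5.0, 3.125), (-1.0, 200.0)])
    def test_printed_values(self, dct, expected):
        assert pemt.exp_transform(dct) == pytest.approx(expected)

    def test_rejects_non_finite(self):
        with pytest.raises(ValueError):
            pemt.exp_transform(np.nan)

    def test_strictly_decreasing(self):
        d = np.linspace(-5, 15, 40)
        assert np.all(np.diff(pemt.exp_transform(d)) < 0)


class TestNval:
    def test_printed_examples(self):
        assert pemt.compute_nval(1.0, 100.0) == pytest.approx(0.0)
        assert pemt.compute_nval(1.0, 1.0) == pytest.approx(1.0)
        assert pemt.compute_nval(3.125, 100.0) == pytest.approx(212.5 / 99.0)

    def test_rejects_inverted_extremes(self):
        with pytest.raises(ValueError):
            pemt.compute_nval(2.0, 1.0)

    @given(
        exp_min=st.floats(1e-3, 1e3),
        ratio=st.floats(1.01, 100.0),
    )
    @settings(max_examples=200, derandomize=True)
    def test_hundred_fold_span_identity(self, exp_min, ratio):
        """(EXP_max - N_val) = 100 * (EXP_min - N_val) whenever extremes differ.

        Pairs are drawn with a bounded EXP_max/EXP_min ratio: the identity is
        algebraic, and bounding the ratio keeps the subtraction away from the
        float cancellation limit so it can be asserted at 1e-9 relative.
        """
        exp_max = exp_min * ratio
        nval = pemt.compute_nval(exp_min, exp_max)
        assert exp_max - nval == pytest.approx(100.0 * (exp_min - nval), rel=1e-9)

    def test_normalized_endpoints_algebra(self):
        lo, hi = 3.125, 100.0
        nval = pemt.compute_nval(lo, hi)
        assert pemt.normalize_gene(lo, nval) == pytest.approx((hi - lo) / 99.0)
        assert pemt.normalize_gene(hi, nval) == pytest.approx(100.0 * (hi - lo) / 99.0)
        assert pemt.normalize_gene(100.0, 0.0) == pytest.approx(100.0)


class TestGenePanel:
    def test_default_panel_is_nine_unique_genes(self):
        panel = pemt.GenePanel()
        assert len(list(panel)) == 9

    @pytest.mark.parametrize(
        "genes",
        [
            ("PDPN",) * 9,  # duplicates
            ("PDPN", "VIM"),  # wrong size
            ("GAPDH",) + pemt.DEFAULT_PANEL[:8],  # reference inside panel
        ],
    )
    def test_invalid_panels_rejected(self, genes):
        with pytest.raises(ValueError):
            pemt.GenePanel(genes)


class TestScore:
    def test_extreme_populations_hit_range_endpoints(self, gradient_ct_table):
        tab, spec = gradient_ct_table
        res = pemt.pemt_score(tab)
        assert res.score_of("HN06") == pytest.approx(10.0)
        assert res.score_of("HN01") == pytest.approx(0.1)

    def test_all_scores_within_bounds(self, gradient_ct_table):
        tab, _ = gradient_ct_table
        s = pemt.pemt_score(tab).scores["score"]
        assert ((s >= 0.1 - 1e-12) & (s <= 10.0 + 1e-12)).all()

    @pytest.mark.parametrize("seed", range(5))
    def test_score_ranking_recovers_generative_gradient(self, seed):
        rng = np.random.default_rng(seed)
        levels = tuple(sorted(rng.uniform(0, 1, size=6)))
        spec = sd.CtGeneratorSpec(
            n_populations=6, pemt_levels=levels, noise_sd_cycles=0.0, seed=seed
        )
        res = pemt.pemt_score(sd.generate_ct_table(spec))
        scores = res.scores["score"].to_numpy()
        rho = spearmanr(levels, scores).statistic
        assert rho == pytest.approx(1.0)

    def test_single_population_rejected(self):
        with pytest.raises(ValueError, match="2 populations"):
            pemt.pemt_score(toy_table({"A": 25.0}))

    def test_degenerate_cohort_scores_midpoint_with_warning(self):
        tab = toy_table({"A": 25.0, "B": 25.0})
        with pytest.warns(UserWarning):
            res = pemt.pemt_score(tab)
        assert np.allclose(res.scores["score"], 5.05)

    def test_degenerate_gene_contributes_zero(self, gradient_ct_table):
        tab, _ = gradient_ct_table
        # pin one gene to the same Ct everywhere
        tab = tab.copy()
        tab.loc[tab.gene_id == "MMP1", "ct"] = 28.0
        with pytest.warns(UserWarning, match="MMP1"):
            res = pemt.pemt_score(tab)
        norm = res.per_gene.xs("MMP1", level="gene_id")["normalized"]
        assert (norm == 0.0).all()

    def test_global_ct_shift_leaves_scores_unchanged(self, gradient_ct_table):
        """Shifting every gene's Ct by the same constant rescales all EXP
        jointly and cancels in the min-max conversion."""
        tab, _ = gradient_ct_table
        base = pemt.pemt_score(tab).scores["score"]
        shifted = tab.copy()
        mask = shifted.gene_id != pemt.REFERENCE_GENE
        shifted.loc[mask, "ct"] += 1.7
        after = pemt.pemt_score(shifted).scores["score"]
        assert np.allclose(base, after)

    def test_per_gene_ct_shift_scales_normalized_values_proportionally(self, gradient_ct_table):
        """The N_val step is affine-equivariant per gene: a constant Ct shift
        multiplies that gene's normalized values by 2**(-c) exactly."""
        tab, _ = gradient_ct_table
        base = pemt.pemt_score(tab).per_gene.xs("VIM", level="gene_id")["normalized"]
        shifted = tab.copy()
        shifted.loc[shifted.gene_id == "VIM", "ct"] += 2.0
        after = pemt.pemt_score(shifted).per_gene.xs("VIM", level="gene_id")["normalized"]
        assert np.allclose(after, base * 2.0**-2.0)

    def test_raising_one_populations_expression_never_lowers_its_score(self, gradient_ct_table):
        tab, _ = gradient_ct_table
        for pop in ("HN01", "HN03", "HN06"):
            before = pemt.pemt_score(tab).score_of(pop)
            bumped = tab.copy()
            sel = (bumped.population_id == pop) & (bumped.gene_id == "PDPN")
            bumped.loc[sel, "ct"] -= 1.0  # lower Ct = higher expression
            after = pemt.pemt_score(bumped).score_of(pop)
            assert after >= before - 1e-12

    def test_replicate_order_invariance(self, gradient_ct_table):
        tab, _ = gradient_ct_table
        shuffled = tab.sample(frac=1.0, random_state=0).reset_index(drop=True)
        a = pemt.pemt_score(tab).scores["score"]
        b = pemt.pemt_score(shuffled).scores["score"]
        assert np.allclose(a, b)
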