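"""Spearman, threshold-split correlations, and binned resampling CIs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from markerrank.errors import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedCorrelationError,
)
from markerrank.stats import binned_ci, binned_ci_frame, spearman, split_correlations


def _rank_then_pearson(x, y):
    """Independent oracle: fractional ranks then Pearson correlation."""
    from scipy.stats import rankdata

    rx = rankdata(x)
    ry = rankdata(y)
    return np.corrcoef(rx, ry)[0, 1]


class TestSpearman:
    def test_monotone_increasing(self):
        res = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert res.rho == pytest.approx(1.0)

    def test_monotone_decreasing(self):
        assert spearman([1, 2, 3, 4], [4, 3, 2, 1]).rho == pytest.approx(-1.0)

    def test_matches_rank_then_pearson(self, rng):
        x = rng.random(10)
        y = rng.random(10)
        assert spearman(x, y).rho == pytest.approx(_rank_then_pearson(x, y), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1, 1], [1, 2, 3, 4])

    def test_too_few_points_rejected(self):
        with pytest.raises(InsufficientDataError):
            spearman([1, 2], [2, 1])

    @given(
        st.lists(
            st.integers(min_value=-100, max_value=100),
            min_size=4, max_size=15, unique=True,
        )
    )
    def test_invariant_under_monotone_transform(self, xs):
        rng = np.random.default_rng(0)
        ys = rng.permutation(len(xs)).astype(float)
        base = spearman(xs, ys).rho
        transformed = spearman([np.exp(x / 50.0) for x in xs], ys).rho
        assert base == pytest.approx(transformed, abs=1e-12)


class TestSplitCorrelations:
    def _frame(self, aai, **genes):
        return pd.DataFrame({"aai": aai, **genes})

    def test_sides_partition_pairs(self):
        rng = np.random.default_rng(1)
        aai = np.concatenate([rng.uniform(80, 94, 10), rng.uniform(96, 100, 10)])
        g = aai + rng.normal(0, 1, 20)
        out = split_correlations(self._frame(aai, gene=g), ["gene"])
        far = out[(out.gene_label == "gene") & (out.side == "far")].iloc[0]
        close = out[(out.gene_label == "gene") & (out.side == "close")].iloc[0]
        assert far.n == 10 and close.n == 10
        assert far.rho > 0.5 and close.rho > 0.5

    def test_constant_gene_flagged(self):
        aai = np.linspace(80, 99, 12)
        out = split_correlations(
            self._frame(aai, flat=np.full(12, 99.0)), ["flat"]
        )
        assert set(out["flag"]) == {"undefined-correlation"}

    def test_threshold_at_boundary_gives_insufficient_side(self):
        aai = np.linspace(50, 90, 12)  # nothing above 95
        out = split_correlations(
            self._frame(aai, g=np.linspace(80, 99, 12)), ["g"], threshold=95.0
        )
        close = out[(out.side == "close")].iloc[0]
        assert close.flag == "insufficient-data"
        assert np.isnan(close.rho)

    def test_invalid_threshold_rejected(self):
        with pytest.raises(InvalidInputError):
            split_correlations(self._frame([90.0], g=[90.0]), ["g"], threshold=100.0)


def _pair_frame(records):
    return pd.DataFrame(records, columns=["genome_a", "genome_b", "identity_16s", "aai"])


class TestBinnedCI:
    def test_constant_aai_gives_point_interval(self):
        recs = _pair_frame(
            [(f"a{i}", f"b{i}", 85.0, 70.0) for i in range(30)]
        )
        out = binned_ci(recs, sample_size=10, seed=1)
        row = [c for c in out if c.n_pairs_in_bin > 0][0]
        assert row.ci_low == pytest.approx(70.0)
        assert row.ci_high == pytest.approx(70.0)

    def test_genome_disjoint_within_sampling(self):
        # 4 genomes -> at most 2 disjoint pairs, flagged short
        genomes = ["g1", "g2", "g3", "g4"]
        recs = _pair_frame(
            [(a, b, 91.0, 80.0) for i, a in enumerate(genomes) for b in genomes[i + 1:]]
        )
        out = binned_ci(recs, sample_size=100, seed=0)
        row = [c for c in out if c.n_pairs_in_bin > 0][0]
        assert row.achieved_size <= 2
        assert row.flag == "short-sample"

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(3)
        recs = _pair_frame(
            [
                (f"x{i}", f"y{i}", float(rng.uniform(80, 100)), float(rng.uniform(40, 100)))
                for i in range(50)
            ]
        )
        f1 = binned_ci_frame(binned_ci(recs, sample_size=5, seed=7))
        f2 = binned_ci_frame(binned_ci(recs, sample_size=5, seed=7))
        pd.testing.assert_frame_equal(f1, f2)

    def test_empty_bin_flagged_not_fatal(self):
        recs = _pair_frame([("a", "b", 80.5, 50.0), ("c", "d", 99.0, 98.0)])
        out = binned_ci(recs, sample_size=1, seed=0)
        flags = {(c.bin_low, c.flag) for c in out}
        assert any(f == "empty-bin" for _, f in flags)
        assert any(f in ("", "short-sample") for _, f in flags)

    def test_disjointness_asserted_directly(self):
        from markerrank.stats import _disjoint_sample

        rng = np.random.default_rng(11)
        pairs = [(f"g{i}", f"g{j}", 1.0) for i in range(10) for j in range(i + 1, 10)]
        for _ in range(5):
            vals = _disjoint_sample(pairs, 100, rng)
            assert len(vals) <= 5  # 10 genomes -> at most 5 disjoint pairs


class TestBroadeningPattern:
    """Among cohorts whose genes' rates drift between clades (relaxed
    clock), the AAI confidence interval is wider in the highest 16s-identity
    bin than in the lowest: near-identical 16s no longer pins down
    genome-wide divergence."""

    @staticmethod
    def _one_seed(seed, tmp):
        import numpy as np

        from markerrank.homology import aai_between
        from markerrank.io import load_cohort
        from markerrank.markers import build_identity_table
        from markerrank.simulate import SimulationConfig, generate_dataset
        from markerrank.stats import binned_ci

        cfg = SimulationConfig(
            n_genomes=9, n_markers=2, n_background_genes=100,
            marker_length_nt=400, slow16s_length_nt=1100, protein_length_aa=60,
            tree_depth=1.2, n_lineages=3, lineage_sizes=(3, 3, 3),
            cluster_size=2, cluster_depth_range=(0.005, 0.1),
            presence_prob=1.0, rate_jitter_sigma=0.5, n_16s_copies=1,
            seed=seed,
        )
        generate_dataset(cfg, tmp)
        genomes = load_cohort(tmp)
        table = build_identity_table(genomes, ["slow16s"])
        proteomes = {g.genome_id: g.proteome for g in genomes}
        rows = []
        for (a, b), vals in table.table.iterrows():
            rec = aai_between(proteomes[a], proteomes[b], a, b, min_homologs=30)
            if rec.aai is not None:
                rows.append((a, b, vals["slow16s"], rec.aai))
        recs = pd.DataFrame(rows, columns=["genome_a", "genome_b", "identity_16s", "aai"])
        cis = binned_ci(recs, sample_size=2, seed=seed)
        widths = [
            (c.bin_low, c.ci_high - c.ci_low)
            for c in cis
            if c.flag != "empty-bin" and np.isfinite(c.ci_low)
        ]
        if len(widths) < 2:
            return None
        return widths[-1][1] >= widths[0][1]  # high-identity vs low-identity bin

    def test_high_identity_bin_wider_in_majority_of_seeds(self, tmp_path):
        outcomes = []
        for seed in range(20):
            d = tmp_path / f"s{seed}"
            result = self._one_seed(seed, d)
            if result is not None:
                outcomes.append(result)
        assert len(outcomes) >= 15
        assert sum(outcomes) > len(outcomes) / 2, outcomes
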