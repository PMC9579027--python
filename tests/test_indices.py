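import numpy as np
import pandas as pd
import pytest

from tailatlas.indices import (
    AnchorStats,
    anchor_correlation_stats,
    categorical_index,
    classify_congruence,
    mesodermal_index,
    naive_index,
    neural_index,
    nm_index_table,
)


def _samples_with_r(r_values, n_cells=50, seed=0):
    """Samples whose per-sample Pearson r(gene, anchor) hit given values."""
    rng = np.random.default_rng(seed)
    out = []
    for r in r_values:
        a = rng.normal(size=n_cells)
        ac = a - a.mean()
        noise = rng.normal(size=n_cells)
        noise -= noise.mean()
        noise -= noise @ ac / (ac @ ac) * ac  # orthogonalize: exact correlation
        g = r * ac / np.std(ac) + np.sqrt(1 - r**2) * noise / np.std(noise)
        out.append({"sox2": a, "gene": g})
    return out


class TestAnchorStats:
    def test_median_iqr_weight(self):
        stats = anchor_correlation_stats(_samples_with_r([0.5, 0.7, 0.9]), ["gene"], "sox2")
        rho, iqr = stats.stats["gene"]
        assert rho == pytest.approx(0.7, abs=1e-9)
        assert iqr == pytest.approx(0.2, abs=1e-9)
        assert stats.weight("gene") == pytest.approx(0.7 * 0.8, abs=1e-9)

    def test_single_sample_zero_iqr(self):
        stats = anchor_correlation_stats(_samples_with_r([0.6]), ["gene"], "sox2")
        rho, iqr = stats.stats["gene"]
        assert iqr == 0.0
        assert stats.weight("gene") == pytest.approx(rho)

    def test_gene_identical_to_anchor(self):
        rng = np.random.default_rng(1)
        samples = [{"sox2": (a := rng.uniform(size=30)), "gene": a.copy()} for _ in range(3)]
        stats = anchor_correlation_stats(samples, ["gene"], "sox2")
        assert stats.stats["gene"] == pytest.approx((1.0, 0.0))

    def test_zero_variance_sample_excluded(self):
        samples = _samples_with_r([0.5, 0.5])
        samples.append({"sox2": np.ones(50), "gene": np.ones(50)})
        with pytest.warns(UserWarning, match="zero variance"):
            stats = anchor_correlation_stats(samples, ["gene"], "sox2")
        assert stats.stats["gene"][0] == pytest.approx(0.5, abs=1e-9)

    def test_all_excluded_raises(self):
        samples = [{"sox2": np.ones(5), "gene": np.arange(5.0)}]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="no sample"):
                anchor_correlation_stats(samples, ["gene"], "sox2")

    def test_affine_rescaling_invariance(self):
        samples = _samples_with_r([0.4, 0.6], seed=2)
        rescaled = [
            {"sox2": s["sox2"], "gene": 3.0 * s["gene"] + 7.0} for s in samples
        ]
        a = anchor_correlation_stats(samples, ["gene"], "sox2")
        b = anchor_correlation_stats(rescaled, ["gene"], "sox2")
        assert a.stats["gene"] == pytest.approx(b.stats["gene"])


class TestIndices:
    def test_empty_sum_reduces_to_anchor(self):
        stats = AnchorStats("sox2", {})
        assert neural_index({"sox2": np.array([0.8])}, stats) == pytest.approx([0.8])

    def test_weighted_sum_example(self):
        stats = AnchorStats("sox2", {"cdh6": (0.8, 0.1)})
        n = neural_index({"sox2": np.array([0.6]), "cdh6": np.array([0.5])}, stats)
        assert n == pytest.approx([0.96])

    def test_mesodermal_example(self):
        stats = AnchorStats("tbxta", {"cdh6": (-0.4, 0.2)})
        m = mesodermal_index({"tbxta": np.array([0.2]), "cdh6": np.array([0.5])}, stats)
        assert m == pytest.approx([0.04])

    def test_nm_is_exact_difference(self):
        rng = np.random.default_rng(0)
        channels = {
            "sox2": rng.uniform(size=40),
            "tbxta": rng.uniform(size=40),
            "cdh6": rng.uniform(size=40),
        }
        ss = AnchorStats("sox2", {"cdh6": (0.5, 0.1)})
        st = AnchorStats("tbxta", {"cdh6": (-0.3, 0.2)})
        table = nm_index_table(channels, ss, st)
        assert np.array_equal(table["NM"].to_numpy(), (table["N"] - table["M"]).to_numpy())

    def test_zero_weights_reduce_to_naive(self):
        rng = np.random.default_rng(1)
        channels = {
            "sox2": rng.uniform(size=20),
            "tbxta": rng.uniform(size=20),
            "cdh6": rng.uniform(size=20),
        }
        ss = AnchorStats("sox2", {"cdh6": (0.0, 0.0)})
        st = AnchorStats("tbxta", {"cdh6": (0.0, 0.0)})
        table = nm_index_table(channels, ss, st)
        assert np.allclose(table["NM"], naive_index(channels))

    def test_anchor_swap_antisymmetry(self):
        rng = np.random.default_rng(2)
        channels = {"sox2": rng.uniform(size=15), "tbxta": rng.uniform(size=15),
                    "cdh6": rng.uniform(size=15)}
        ss = AnchorStats("sox2", {"cdh6": (0.6, 0.1)})
        st = AnchorStats("tbxta", {"cdh6": (0.6, 0.1)})
        table = nm_index_table(channels, ss, st)
        swapped = {**channels, "sox2": channels["tbxta"], "tbxta": channels["sox2"]}
        table2 = nm_index_table(swapped, ss, st)
        assert np.allclose(table2["NM"], -table["NM"])

    def test_missing_stats_gene_raises(self):
        with pytest.raises(KeyError, match="cdh6"):
            neural_index(
                {"sox2": np.array([0.5]), "cdh6": np.array([0.5])},
                AnchorStats("sox2", {}),
            )


class TestAlternativeIndices:
    def test_naive(self):
        out = naive_index({"sox2": np.array([0.8]), "tbxta": np.array([0.3])})
        assert out == pytest.approx([0.5])

    def test_naive_range(self):
        rng = np.random.default_rng(0)
        out = naive_index({"sox2": rng.uniform(size=100), "tbxta": rng.uniform(size=100)})
        assert out.min() >= -1 and out.max() <= 1

    def test_categorical_and_antisymmetry(self):
        c = {"sox2": np.array([1.0]), "cdh6": np.array([1.0]),
             "tbxta": np.array([0.0]), "tcf": np.array([0.0])}
        assert categorical_index(c) == pytest.approx([2.0])
        swapped = {"sox2": c["tbxta"], "cdh6": c["tcf"], "tbxta": c["sox2"], "tcf": c["cdh6"]}
        assert categorical_index(swapped) == pytest.approx([-2.0])
        same = {k: np.array([0.4]) for k in c}
        assert categorical_index(same) == pytest.approx([0.0])


class TestClassification:
    def _table(self, nm, domain):
        return pd.DataFrame({"N": nm, "M": np.zeros(len(nm)), "NM": nm, "domain": domain})

    @pytest.mark.parametrize(
        "nm,domain,tcf,expected",
        [
            (0.4, "neural-fated", 0.2, "Congruent"),
            (0.4, "mesoderm-fated", 0.2, "Compliant"),   # tcf agrees with neural state
            (0.4, "mesoderm-fated", 0.9, "Rebellious"),  # tcf contradicts neural state
            (-0.4, "mesoderm-fated", 0.9, "Congruent"),
            (-0.4, "neural-fated", 0.9, "Compliant"),
            (-0.4, "neural-fated", 0.2, "Rebellious"),
        ],
    )
    def test_rule_table(self, nm, domain, tcf, expected):
        table = self._table([nm], [domain])
        out = classify_congruence(table, np.array([tcf]), tcf_threshold=0.5)
        assert out["congruence"].iloc[0] == expected

    def test_neutral_band_leaves_unassigned(self):
        table = self._table([0.05, -0.05, 0.5], ["neural-fated"] * 3)
        out = classify_congruence(table, np.array([0.1] * 3), nm_band=0.1, tcf_threshold=0.5)
        assert list(out["congruence"][:2]) == ["unassigned", "unassigned"]
        assert out["congruence"].iloc[2] == "Congruent"

    def test_classification_exhaustive_exclusive(self):
        rng = np.random.default_rng(3)
        n = 200
        table = self._table(
            rng.normal(size=n), rng.choice(["neural-fated", "mesoderm-fated"], size=n)
        )
        out = classify_congruence(table, rng.uniform(size=n), nm_band=0.2)
        counts = out["congruence"].value_counts()
        assert counts.sum() == n
        assert set(counts.index) <= {"Congruent", "Compliant", "Rebellious", "unassigned"}

    def test_missing_domain_raises(self):
        table = pd.DataFrame({"NM": [0.1]})
        with pytest.raises(ValueError, match="domain"):
            classify_congruence(table, np.array([0.5]))


def test_naive_tracks_full_index_on_synthetic_nmps():
    """With field-realistic weights the naive and full NM indices co-move."""
    rng = np.random.default_rng(4)
    n = 500
    channels = {"sox2": rng.uniform(size=n), "tbxta": rng.uniform(size=n)}
    ss_stats, st_stats = {}, {}
    for gene in ("cdh6", "hes6", "sp5l", "tagln3b", "znf703", "tcf"):
        rho_s = rng.uniform(-0.5, 0.7)
        rho_t = rng.uniform(-0.7, 0.5)
        channels[gene] = np.clip(
            0.5 + 0.4 * rho_s * (channels["sox2"] - 0.5)
            + 0.4 * rho_t * (channels["tbxta"] - 0.5)
            + rng.normal(scale=0.15, size=n),
            0, 1,
        )
        ss_stats[gene] = (rho_s, rng.uniform(0.05, 0.3))
        st_stats[gene] = (rho_t, rng.uniform(0.05, 0.3))
    table = nm_index_table(
        channels, AnchorStats("sox2", ss_stats), AnchorStats("tbxta", st_stats)
    )
    r = np.corrcoef(table["NM"], naive_index(channels))[0, 1]
    assert r > 0.7
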