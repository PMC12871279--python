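import anndata as ad
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ranksums

from spotkit import (
    QcThresholds,
    apply_quality_filter,
    build_incongruent_pairs,
    compute_cell_metrics,
    derive_division_markers,
    incongruent_fraction,
)


def _adata(counts, blanks=None, volume=None):
    counts = np.asarray(counts)
    obs = pd.DataFrame(index=[f"c{i}" for i in range(counts.shape[0])])
    if blanks is not None:
        obs["n_blanks"] = blanks
    if volume is not None:
        obs["volume_um3"] = volume
    return ad.AnnData(X=counts, obs=obs,
                      var=pd.DataFrame(index=[f"G{j}" for j in range(counts.shape[1])]))


class TestMetrics:
    def test_hand_arithmetic(self):
        adata = _adata([[10, 5]], blanks=[1])
        m = compute_cell_metrics(adata)
        assert m["n_genes"].iloc[0] == 2
        assert m["n_transcripts"].iloc[0] == 15
        assert m["blank_fraction"].iloc[0] == pytest.approx(1 / 16)

    def test_no_blanks(self):
        m = compute_cell_metrics(_adata([[3, 3]], blanks=[0]))
        assert m["blank_fraction"].iloc[0] == 0.0

    def test_density(self):
        m = compute_cell_metrics(_adata([[10, 0]], blanks=[0], volume=[20.0]))
        assert m["density"].iloc[0] == pytest.approx(0.5)

    def test_zero_volume_density_undefined(self):
        m = compute_cell_metrics(_adata([[10, 0]], blanks=[0], volume=[0.0]))
        assert np.isnan(m["density"].iloc[0])


class TestQualityFilter:
    @pytest.mark.parametrize(
        "n_genes,n_tx,blank_frac,kept",
        [
            (5, 100, 0.0, False),   # below the 6-gene floor
            (6, 30, 0.019, True),   # exactly at the floors, blanks below the cap
            (50, 200, 0.025, False),  # blank fraction at/above 2%
            (6, 29, 0.0, False),
            (7, 31, 0.02, False),   # boundary: >= cap removes
        ],
    )
    def test_boundaries(self, n_genes, n_tx, blank_frac, kept):
        metrics = pd.DataFrame(
            {"n_genes": [n_genes], "n_transcripts": [n_tx], "blank_fraction": [blank_frac]}
        )
        assert apply_quality_filter(metrics).iloc[0] == kept

    @settings(max_examples=50, deadline=None)
    @given(
        g=st.integers(0, 20), tx=st.integers(0, 200),
        bf=st.floats(0, 1), dg=st.integers(0, 6), dtx=st.integers(0, 30),
    )
    def test_filter_monotone_in_thresholds(self, g, tx, bf, dg, dtx):
        """Lowering a threshold never removes a previously retained cell."""
        metrics = pd.DataFrame({"n_genes": [g], "n_transcripts": [tx], "blank_fraction": [bf]})
        strict = QcThresholds()
        loose = QcThresholds(min_genes=strict.min_genes - min(dg, 6),
                             min_transcripts=strict.min_transcripts - min(dtx, 30),
                             max_blank_fraction=strict.max_blank_fraction)
        if apply_quality_filter(metrics, strict).iloc[0]:
            assert apply_quality_filter(metrics, loose).iloc[0]

    def test_planted_low_quality_recovered(self, small_section):
        from spotkit.core import make_spot_table
        cfg, spots, dapi, truth = small_section
        # score each planted cell from its own true transcripts: the plant is
        # recovered exactly under the stated rule
        removed = set()
        for cid, group in spots.dropna(subset=["true_cell"]).groupby("true_cell"):
            nb = group[~group["is_blank"]]
            n_genes = nb["gene"].nunique()
            n_tx = len(nb)
            bf = group["is_blank"].sum() / len(group)
            metrics = pd.DataFrame({"n_genes": [n_genes], "n_transcripts": [n_tx], "blank_fraction": [bf]})
            if not apply_quality_filter(metrics).iloc[0]:
                removed.add(cid)
        assert set(truth.low_quality) == removed


class TestMarkers:
    def test_exclusive_gene_is_top_marker(self):
        medians = pd.DataFrame(
            {"Ga": [5.0, 6.0, 0.0, 0.0], "Gb": [0.0, 0.0, 4.0, 5.0], "Gc": [1.0, 1.0, 1.0, 1.0]},
            index=["k1", "k2", "k3", "k4"],
        )
        division_of = {"k1": "A", "k2": "A", "k3": "B", "k4": "B"}
        markers = derive_division_markers(medians, division_of, top_n=1)
        assert markers["A"] == ["Ga"]
        assert markers["B"] == ["Gb"]
        # oracle: the rank-sum statistic itself prefers Ga for A
        sa = ranksums(medians.loc[["k1", "k2"], "Ga"], medians.loc[["k3", "k4"], "Ga"]).statistic
        sc = ranksums(medians.loc[["k1", "k2"], "Gc"], medians.loc[["k3", "k4"], "Gc"]).statistic
        assert sa > sc

    def test_constant_gene_never_marker(self):
        medians = pd.DataFrame(
            {"Ga": [5.0, 0.0], "Gb": [0.0, 5.0], "Gflat": [2.0, 2.0]}, index=["k1", "k2"]
        )
        markers = derive_division_markers(medians, {"k1": "A", "k2": "B"}, top_n=1)
        assert "Gflat" not in markers["A"] + markers["B"]

    def test_top_n_capped_at_panel(self, caplog):
        medians = pd.DataFrame({"Ga": [5.0, 0.0], "Gb": [0.0, 5.0]}, index=["k1", "k2"])
        markers = derive_division_markers(medians, {"k1": "A", "k2": "B"}, top_n=10)
        assert sorted(markers["A"]) == ["Ga", "Gb"]


class TestIncongruent:
    def _setup(self):
        markers = {"A": ["Ga1", "Ga2"], "B": ["Gb1"]}
        pairs = build_incongruent_pairs(markers)
        marker_division = {"Ga1": "A", "Ga2": "A", "Gb1": "B"}
        return pairs, marker_division

    def test_own_markers_only_is_zero(self):
        pairs, md = self._setup()
        adata = _adata([[5, 5, 0]])
        adata.var_names = ["Ga1", "Ga2", "Gb1"]
        out = incongruent_fraction(adata, pairs, pd.Series(["A"], index=adata.obs.index), md)
        assert out.iloc[0] == 0.0

    def test_twenty_percent(self):
        pairs, md = self._setup()
        adata = _adata([[4, 4, 2]])  # 8 own-division + 2 incongruent
        adata.var_names = ["Ga1", "Ga2", "Gb1"]
        out = incongruent_fraction(adata, pairs, pd.Series(["A"], index=adata.obs.index), md)
        assert out.iloc[0] == pytest.approx(20.0)

    def test_zero_transcript_cell_undefined(self):
        pairs, md = self._setup()
        adata = _adata([[0, 0, 0]])
        adata.var_names = ["Ga1", "Ga2", "Gb1"]
        out = incongruent_fraction(adata, pairs, pd.Series(["A"], index=adata.obs.index), md)
        assert np.isnan(out.iloc[0])

    def test_pairs_never_within_division(self):
        pairs, _ = self._setup()
        assert frozenset(("Ga1", "Ga2")) not in pairs
        assert frozenset(("Ga1", "Gb1")) in pairs
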