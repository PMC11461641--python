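"""Molecular stages: QC filtering, demultiplexing, signature scoring,
annotation, rank-based DE and over-representation."""

import math

import anndata as ad
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from fdgmismatch.errors import InsufficientDataError, ValidationError
from fdgmismatch.immune import (
    annotate_and_count,
    annotate_cells,
    cpm_log1p,
    de_test,
    demux_hashtags,
    ora_enrich,
    qc_filter_nuclei,
    signature_score,
)
from fdgmismatch.signatures import CELL_TYPE_SIGNATURES, MITO_GENES, SignatureSet
from fdgmismatch.synthetic import NucleiConfig, simulate_nuclei


def build_cells(counts: np.ndarray, genes: list[str], **obs_cols) -> ad.AnnData:
    obs = pd.DataFrame(obs_cols, index=[f"c{i}" for i in range(counts.shape[0])])
    return ad.AnnData(X=sparse.csr_matrix(counts), obs=obs,
                      var=pd.DataFrame(index=genes))


class TestQcFilter:
    def make_boundary_matrix(self):
        # 250 non-mito genes + 13 mito genes; craft detected/mito per cell
        genes = [f"G{i:03d}" for i in range(250)] + list(MITO_GENES)
        rows = []
        # (n detected non-mito genes, mito counts) per cell
        specs = [(200, 0), (199, 0), (250, 0), (100, 0),
                 (220, 55), (220, 56), (240, 500)]
        for detected, mito in specs:
            row = np.zeros(len(genes))
            row[:detected] = 1
            if mito:
                row[250] = mito  # all mito mass on ND1
            rows.append(row)
        return np.array(rows), genes, specs

    def test_boundary_cells(self):
        X, genes, _ = self.make_boundary_matrix()
        adata = build_cells(X, genes)
        kept, report = qc_filter_nuclei(adata)
        names = list(kept.obs_names)
        assert "c0" in names     # exactly 200 genes: retained (inclusive)
        assert "c1" not in names  # 199 genes: removed
        # c4: 220 detected + ND1 = 221 genes, mito 55/275 = 0.2 exactly: retained
        assert "c4" in names
        # c5: mito 56/276 > 0.2: removed
        assert "c5" not in names
        assert report["n_input"] == 7

    def test_matches_bruteforce_rule_oracle(self, rng):
        genes = [f"G{i:03d}" for i in range(300)] + list(MITO_GENES)
        X = rng.poisson(0.8, size=(50, len(genes)))
        X[:, 300:] = rng.poisson(rng.uniform(0, 30, (50, 1)), size=(50, 13))
        adata = build_cells(X, genes)
        kept, _ = qc_filter_nuclei(adata)
        survivors = set(kept.obs_names)
        for i in range(50):
            detected = int((X[i] > 0).sum())
            mito = X[i, 300:].sum() / max(X[i].sum(), 1)
            expected = detected >= 200 and mito <= 0.20
            assert (f"c{i}" in survivors) == expected, f"cell {i}"

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValidationError):
            qc_filter_nuclei(build_cells(np.zeros((0, 3)), ["a", "b", "c"]))


class TestDemux:
    def simulate_tags(self, rng, n_cells=400, separation_ok=True):
        tags = ["A", "B", "C"]
        true = rng.integers(3, size=n_cells)
        bg = rng.lognormal(np.log(8), 0.5, (n_cells, 3))
        sig = rng.lognormal(np.log(400), 0.4, n_cells)
        counts = bg
        counts[np.arange(n_cells), true] = sig
        return pd.DataFrame(np.rint(counts), index=[f"c{i}" for i in range(n_cells)],
                            columns=tags), np.array(tags)[true]

    def test_recovery_on_well_separated_mixtures(self, rng):
        counts, truth = self.simulate_tags(rng)
        result, fits = demux_hashtags(counts, seed=0)
        assert all(f.converged for f in fits)
        assert (result["assignment"] == truth).mean() >= 0.98

    def test_trivial_rules(self, rng):
        counts, _ = self.simulate_tags(rng, n_cells=100)
        counts.iloc[0] = [0, 0, 0]          # no signal anywhere
        counts.iloc[1] = [2000, 2000, 5]    # strong on two tags
        result, _ = demux_hashtags(counts, seed=0)
        assert result["assignment"].iloc[0] == "negative"
        assert result["assignment"].iloc[1] == "doublet"

    def test_input_contracts(self):
        with pytest.raises(ValidationError):
            demux_hashtags(pd.DataFrame({"A": [1, 2, 3]}))
        with pytest.raises(InsufficientDataError):
            demux_hashtags(pd.DataFrame({"A": [1] * 5, "B": [2] * 5}))


class TestSignatureScore:
    def make_counts(self, rng, n_samples=8):
        genes = [f"G{i:03d}" for i in range(50)] + ["M1", "M2", "M3", "M4"]
        counts = rng.poisson(50, (len(genes), n_samples))
        return pd.DataFrame(counts, index=genes,
                            columns=[f"s{j}" for j in range(n_samples)])

    def test_constant_signature_scores_zero_after_standardizing(self):
        genes = [f"G{i:03d}" for i in range(10)] + ["M1", "M2", "M3"]
        counts = pd.DataFrame(7, index=genes, columns=["s0", "s1", "s2", "s3"])
        out = signature_score(counts, SignatureSet({"T": ["M1", "M2", "M3"]}))
        # equal library sizes: every sample has log1p-CPM of the constant
        expected = np.log1p(7 / (7 * len(genes)) * 1e6)
        assert out["scores"].loc["T"].to_numpy() == pytest.approx(expected)
        assert out["zscores"].loc["T"].to_numpy() == pytest.approx(0.0)

    def test_spiked_sample_has_maximal_score(self, rng):
        counts = self.make_counts(rng)
        counts.loc[["M1", "M2", "M3", "M4"], "s3"] *= 10
        out = signature_score(counts, SignatureSet({"Mono": ["M1", "M2", "M3", "M4"]}))
        assert out["scores"].loc["Mono"].idxmax() == "s3"

    def test_anticorrelated_decoy_dropped(self, rng):
        counts = self.make_counts(rng)
        trend = np.array([1, 2, 4, 8, 16, 32, 64, 128])
        for m in ("M1", "M2", "M3"):
            counts.loc[m] = 20 * trend
        counts.loc["M4"] = 20 * trend[::-1]  # runs against the signature trend
        out = signature_score(counts, SignatureSet({"Mono": ["M1", "M2", "M3", "M4"]}))
        assert "M4" not in out["surviving_genes"]["Mono"]
        assert set(out["surviving_genes"]["Mono"]) == {"M1", "M2", "M3"}

    def test_invariant_to_library_rescaling(self, rng):
        counts = self.make_counts(rng)
        sigs = SignatureSet({"Mono": ["M1", "M2", "M3", "M4"]})
        scaled = (counts * np.array([1, 2, 5, 1, 3, 1, 4, 2])).astype(int)
        s0 = signature_score(counts, sigs)["scores"]
        # integer scaling keeps CPM exact, so scores match to rounding
        s1 = signature_score(scaled, sigs)["scores"]
        np.testing.assert_allclose(s0.to_numpy(), s1.to_numpy(), rtol=1e-12)

    def test_too_few_genes_reported_not_dropped(self, rng):
        counts = self.make_counts(rng)
        out = signature_score(
            counts, SignatureSet({"Mono": ["M1", "M2", "M3", "M4"],
                                  "Ghost": ["Z1", "Z2", "Z3"]})
        )
        assert out["not_scorable"] == ["Ghost"]


class TestAnnotate:
    def test_pure_marker_cell_labeled(self):
        genes = ["A1", "A2", "B1", "B2"]
        sigs = SignatureSet({"TypeA": ["A1", "A2"], "TypeB": ["B1", "B2"]})
        X = np.array([[50, 40, 0, 0], [0, 0, 30, 60]])
        adata = build_cells(X, genes, region=["r", "r"], group=["g", "g"])
        labels = annotate_cells(adata, sigs)
        assert list(labels) == ["TypeA", "TypeB"]

    def test_exact_tie_is_unassigned(self):
        genes = ["A1", "B1"]
        sigs = SignatureSet({"TypeA": ["A1"], "TypeB": ["B1"]})
        adata = build_cells(np.array([[25, 25]]), genes, region=["r"], group=["g"])
        assert annotate_cells(adata, sigs).iloc[0] == "unassigned"

    def test_recovery_on_synthetic_nuclei(self, nuclei_config):
        adata = simulate_nuclei(nuclei_config, "Border", "Mismatch", 1200, seed=31)
        labels, table = annotate_and_count(adata, CELL_TYPE_SIGNATURES)
        truth = adata.obs["true_type"]
        per_type = (
            pd.DataFrame({"true": truth.to_numpy(), "ok": labels.to_numpy() == truth.to_numpy()})
            .groupby("true")["ok"].mean()
        )
        assert per_type.mean() >= 0.90  # macro-averaged recovery
        # the count table covers every (type, present arm) combination
        assert {"cell_type", "region", "group", "count", "percent"} <= set(table.columns)
        totals = table.groupby(["region", "group"])["percent"].sum()
        assert totals.to_numpy() == pytest.approx(100.0)

    def test_no_signatures_is_usage_error(self, nuclei_config):
        adata = simulate_nuclei(nuclei_config, "Border", "Match", 30, seed=1)
        with pytest.raises(ValidationError):
            annotate_cells(adata, SignatureSet({"X": ["NOPE1", "NOPE2"]}))


class TestDeTest:
    def make_two_arms(self, rng, n=30, n_genes=40, shift_gene=None):
        genes = [f"G{i:03d}" for i in range(n_genes)]
        X = rng.poisson(5, (2 * n, n_genes)).astype(float)
        if shift_gene is not None:
            X[n:, shift_gene] *= 6
        return build_cells(X, genes, group=["Match"] * n + ["Mismatch"] * n,
                           region=["Border"] * 2 * n)

    def test_shifted_gene_detected(self, rng):
        adata = self.make_two_arms(rng, shift_gene=7)
        res = de_test(adata, ("Mismatch", "Match"))
        assert res.loc[7, "p_adj"] < 0.05
        assert res.loc[7, "log2fc"] > 0

    def test_all_zero_gene_null_result(self, rng):
        adata = self.make_two_arms(rng)
        X = adata.X.toarray()
        X[:, 3] = 0
        adata.X = sparse.csr_matrix(X)
        res = de_test(adata, ("Mismatch", "Match"))
        assert res.loc[3, "p"] == 1.0 and res.loc[3, "log2fc"] == 0.0

    def test_bh_toy_oracle(self):
        from statsmodels.stats.multitest import multipletests

        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.5], method="fdr_bh")
        assert adj == pytest.approx([0.04, 0.04, 0.04, 0.5])

    def test_small_arm_rejected_naming_contrast(self, rng):
        adata = self.make_two_arms(rng, n=4)
        with pytest.raises(InsufficientDataError, match="Mismatch vs Match"):
            de_test(adata, ("Mismatch", "Match"))


class TestOra:
    def test_pathway_equal_to_degs_is_top_hit(self):
        universe = {f"g{i}" for i in range(200)}
        degs = {"g1", "g2", "g3", "g4", "g5"}
        pathways = {"hit": set(degs), "noise": {f"g{i}" for i in range(50, 70)}}
        res = ora_enrich(degs, pathways, universe)
        assert res.iloc[0]["pathway"] == "hit"
        assert res.iloc[0]["p"] < 1e-8

    def test_zero_overlap_p_is_one(self):
        universe = {f"g{i}" for i in range(30)}
        res = ora_enrich({"g0", "g1"}, {"pw": {"g20", "g21"}}, universe)
        assert res["p"].iloc[0] == pytest.approx(1.0)

    def test_matches_exact_enumeration_small_universe(self):
        # universe 20, pathway 5, DEGs 5, overlap 3
        universe = {f"g{i}" for i in range(20)}
        pathway = {f"g{i}" for i in range(5)}
        degs = {"g0", "g1", "g2", "g10", "g11"}
        res = ora_enrich(degs, {"pw": pathway}, universe)
        # exact tail: P(X >= 3) for hypergeom(N=20, K=5, n=5)
        expected = sum(
            math.comb(5, k) * math.comb(15, 5 - k) for k in (3, 4, 5)
        ) / math.comb(20, 5)
        assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_exhaustive_small_instances(self, rng):
        # every instance with universe <= 25 must match combinatorial enumeration
        for _ in range(25):
            N = int(rng.integers(5, 26))
            uni = [f"g{i}" for i in range(N)]
            K = int(rng.integers(1, N + 1))
            n = int(rng.integers(1, N + 1))
            pathway = set(rng.choice(uni, K, replace=False))
            degs = set(rng.choice(uni, n, replace=False))
            k_obs = len(pathway & degs)
            res = ora_enrich(degs, {"pw": pathway}, set(uni))
            expected = sum(
                math.comb(K, k) * math.comb(N - K, n - k)
                for k in range(k_obs, min(K, n) + 1)
            ) / math.comb(N, n)
            assert res["p"].iloc[0] == pytest.approx(expected, rel=1e-10)

    def test_empty_deg_warns_all_ones(self):
        with pytest.warns(UserWarning):
            res = ora_enrich(set(), {"pw": {"g1"}}, {"g1", "g2"})
        assert (res["p"] == 1.0).all()
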