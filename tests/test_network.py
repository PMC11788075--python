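"""Network construction: adjacency, TOM (vs brute force), consensus
calibration, module detection, eigengenes and timing categories."""
import numpy as np
import pandas as pd
import pytest

from dielmat.network import (
    build_consensus_modules,
    calibrate_and_consensus,
    categorize_timing,
    detect_modules,
    eigengene,
    module_composition,
    signed_adjacency,
    tom,
)
from dielmat.synthetic import SampleDesign
from dielmat.timing import PhaseWindows


def _expr(arr, prefix="g"):
    arr = np.asarray(arr, dtype=float)
    return pd.DataFrame(
        arr,
        index=[f"{prefix}{i}" for i in range(arr.shape[0])],
        columns=[f"s{i}" for i in range(arr.shape[1])],
    )


def _random_adjacency(n, rng):
    r = rng.uniform(0, 1, size=(n, n))
    a = (r + r.T) / 2
    np.fill_diagonal(a, 1.0)
    idx = [f"g{i}" for i in range(n)]
    return pd.DataFrame(a, index=idx, columns=idx)


def tom_brute_force(a: np.ndarray) -> np.ndarray:
    """Reference triple-loop evaluation of the topological overlap formula."""
    n = a.shape[0]
    out = np.ones((n, n))
    k = np.array([sum(a[i, u] for u in range(n) if u != i) for i in range(n)])
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            shared = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (shared + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestSignedAdjacency:
    def test_closed_forms(self):
        x = np.arange(6, dtype=float)
        expr = _expr([x, x * 2 + 1, -x])  # r = 1 and r = -1
        a = signed_adjacency(expr, beta=18)
        assert a.iloc[0, 1] == pytest.approx(1.0)
        assert a.iloc[0, 2] == pytest.approx(0.0)

    def test_zero_correlation_value(self, rng):
        # orthogonal sign patterns give r = 0 exactly
        expr = _expr([[1, -1, 1, -1], [1, 1, -1, -1]])
        a = signed_adjacency(expr, beta=18)
        assert a.iloc[0, 1] == pytest.approx(0.5**18, rel=1e-12)

    def test_monotone_in_correlation(self, rng):
        expr = _expr(rng.normal(size=(10, 8)))
        r = np.corrcoef(expr.to_numpy())
        a = signed_adjacency(expr, beta=18).to_numpy()
        iu = np.triu_indices(10, k=1)
        order_r = np.argsort(r[iu])
        assert (np.diff(a[iu][order_r]) > 0).all()

    def test_constant_gene_rejected_by_name(self):
        expr = _expr([[1, 2, 3, 4], [5, 5, 5, 5]])
        with pytest.raises(ValueError, match="g1"):
            signed_adjacency(expr)


class TestTom:
    def test_two_gene_closed_form(self):
        for a12 in (0.1, 0.5, 0.9):
            adj = pd.DataFrame(
                [[1.0, a12], [a12, 1.0]], index=["g0", "g1"], columns=["g0", "g1"]
            )
            assert tom(adj).iloc[0, 1] == pytest.approx(a12, abs=1e-12)

    def test_all_ones_adjacency(self):
        idx = [f"g{i}" for i in range(5)]
        adj = pd.DataFrame(np.ones((5, 5)), index=idx, columns=idx)
        assert np.allclose(tom(adj).to_numpy(), 1.0)

    @pytest.mark.parametrize("n", [6, 9, 12])
    def test_matches_brute_force(self, n, rng):
        adj = _random_adjacency(n, rng)
        fast = tom(adj).to_numpy()
        slow = tom_brute_force(adj.to_numpy())
        np.testing.assert_allclose(fast, np.clip(slow, 0, 1), atol=1e-12)

    def test_bounded_on_random_adjacencies(self, rng):
        for _ in range(100):
            t = tom(_random_adjacency(7, rng)).to_numpy()
            assert (t >= 0).all() and (t <= 1 + 1e-12).all()


class TestConsensus:
    def test_identical_inputs_are_fixed_point(self, rng):
        t1 = tom(_random_adjacency(8, rng))
        cons = calibrate_and_consensus([t1, t1.copy(), t1.copy()])
        pd.testing.assert_frame_equal(cons, t1)

    def test_consensus_dominates(self, rng):
        toms = [tom(_random_adjacency(8, rng)) for _ in range(3)]
        n = 8
        iu = np.triu_indices(n, k=1)
        qs = [np.quantile(t.to_numpy()[iu], 0.95) for t in toms]
        target = np.mean(qs)
        cons = calibrate_and_consensus(toms).to_numpy()
        for t, q in zip(toms, qs):
            calibrated = np.clip(t.to_numpy() * target / q, 0, 1)
            np.fill_diagonal(calibrated, 1.0)
            assert (cons <= calibrated + 1e-12).all()

    def test_scale_cancellation(self, rng):
        t1 = tom(_random_adjacency(8, rng))
        half = t1 * 0.5
        cons = calibrate_and_consensus([t1, half])
        # after calibration both series coincide with neither rescaled beyond
        # their common quantile mean; consensus = calibrated series1
        iu = np.triu_indices(8, k=1)
        q1 = np.quantile(t1.to_numpy()[iu], 0.95)
        target = np.mean([q1, q1 * 0.5])
        expected = np.clip(t1.to_numpy() * target / q1, 0, 1)
        np.fill_diagonal(expected, 1.0)
        np.testing.assert_allclose(cons.to_numpy(), expected, atol=1e-12)

    def test_gene_mismatch_rejected(self, rng):
        t1 = tom(_random_adjacency(6, rng))
        t2 = t1.copy()
        t2.index = t2.columns = [f"h{i}" for i in range(6)]
        with pytest.raises(ValueError, match="identical"):
            calibrate_and_consensus([t1, t2])


class TestEigengene:
    def test_identical_profiles(self):
        profile = np.array([1.0, -1.0, 2.0, -2.0])
        block = _expr(np.tile(profile, (6, 1)))
        e, var = eigengene(block)
        assert var == pytest.approx(1.0)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(e, z / np.linalg.norm(z))

    def test_matches_covariance_eigendecomposition(self, rng):
        block = _expr(rng.normal(size=(20, 8)))
        e, _ = eigengene(block)
        x = block.to_numpy()
        x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
        w, v = np.linalg.eigh(x.T @ x)
        top = v[:, np.argmax(w)]
        assert np.allclose(np.abs(e), np.abs(top), atol=1e-10)
        assert np.linalg.norm(e) == pytest.approx(1.0)

    def test_never_anticorrelated_with_mean_profile(self, rng):
        for _ in range(20):
            block = _expr(rng.normal(size=(10, 6)))
            e, _ = eigengene(block)
            x = block.to_numpy()
            x = (x - x.mean(axis=1, keepdims=True)) / x.std(axis=1, keepdims=True)
            assert float(e @ x.mean(axis=0)) >= -1e-12

    def test_single_sample_rejected(self):
        with pytest.raises(ValueError):
            eigengene(_expr([[1.0]]))


def _block_expr(rng, sizes, n_samples=12, noise=0.0):
    """Genes in the same block share one latent profile exactly (r = 1)."""
    rows = []
    for b, size in enumerate(sizes):
        latent = rng.normal(size=n_samples)
        for g in range(size):
            scale = rng.uniform(0.5, 2)
            rows.append(latent * scale + rng.normal(0, noise, n_samples))
    return _expr(np.array(rows))


class TestDetectModules:
    def test_two_planted_blocks_recovered_exactly(self, rng):
        expr = _block_expr(rng, [35, 30])
        adj = signed_adjacency(expr)
        modules = detect_modules(tom(adj), {"S1": expr})
        assert set(modules.sizes.index) == {"ME1", "ME2"}
        assert modules.sizes["ME1"] == 35 and modules.sizes["ME2"] == 30
        got = modules.assignment
        assert got.iloc[:35].nunique() == 1 and got.iloc[35:].nunique() == 1

    def test_small_block_lands_in_unassigned(self, rng):
        expr = _block_expr(rng, [40, 10])
        modules = detect_modules(tom(signed_adjacency(expr)), {"S1": expr})
        assert modules.sizes.get("ME0", 0) == 10
        assert (modules.assignment.iloc[40:] == "ME0").all()

    def test_correlated_blocks_merged(self, rng):
        # two blocks driven by the same latent curve plus tiny noise: their
        # eigengenes correlate far above 1 - merge_cut, so one module remains
        latent = rng.normal(size=12)
        rows = [latent * rng.uniform(0.5, 2) + rng.normal(0, 0.05, 12) for _ in range(70)]
        expr = _expr(np.array(rows))
        modules = detect_modules(
            tom(signed_adjacency(expr)), {"S1": expr}, merge_cut=0.25
        )
        assert len(modules.modules()) == 1

    def test_tiny_input_all_unassigned(self, rng):
        expr = _expr(rng.normal(size=(5, 8)))
        modules = detect_modules(tom(signed_adjacency(expr)), {"S1": expr})
        assert (modules.assignment == "ME0").all()

    def test_gene_order_permutation_consistent(self, rng):
        expr = _block_expr(rng, [32, 31])
        perm = rng.permutation(len(expr))
        shuffled = expr.iloc[perm]
        m1 = detect_modules(tom(signed_adjacency(expr)), {"S1": expr})
        m2 = detect_modules(tom(signed_adjacency(shuffled)), {"S1": shuffled})
        a1 = m1.assignment.sort_index()
        a2 = m2.assignment.sort_index()
        # same partition, labels possibly swapped only between equal sizes
        tab = pd.crosstab(a1, a2)
        assert (tab.to_numpy() > 0).sum() == len(tab)


class TestCompositionAndTiming:
    def test_dominant_fraction(self, small_catalog):
        genes_a = small_catalog.index[small_catalog["taxon"] == "taxA"][:6]
        genes_b = small_catalog.index[small_catalog["taxon"] == "taxB"][:4]
        from dielmat.network import ModuleSet

        assignment = pd.Series("ME1", index=list(genes_a) + list(genes_b)[:3])
        assignment.loc[genes_b[3]] = "ME2"
        ms = ModuleSet(assignment=assignment, eigengenes={},
                       sizes=assignment.value_counts())
        summary, spectrum = module_composition(ms, small_catalog)
        assert summary.loc["ME1", "dominant_taxon"] == "taxA"
        assert summary.loc["ME1", "dominant_fraction"] == pytest.approx(6 / 9)
        assert summary.loc["ME2", "dominant_fraction"] == 1.0
        assert spectrum.loc["taxA", "ME1"] == pytest.approx(1.0)

    def test_timing_agreement_and_disagreement(self):
        from dielmat.network import ModuleSet

        times = np.arange(0, 24, 2.0)
        designs = {
            s: SampleDesign(s, times, sunrise=6.0, sunset=19.0)
            for s in ("A", "B", "C")
        }

        def eg_peaking(at):
            v = np.exp(-0.5 * ((times - at) / 2.0) ** 2)
            return v / np.linalg.norm(v)

        eigengenes = {
            "A": pd.DataFrame([eg_peaking(12), eg_peaking(12)], index=["ME1", "ME2"],
                              columns=designs["A"].sample_names),
            "B": pd.DataFrame([eg_peaking(10), eg_peaking(12)], index=["ME1", "ME2"],
                              columns=designs["B"].sample_names),
            "C": pd.DataFrame([eg_peaking(12), eg_peaking(2)], index=["ME1", "ME2"],
                              columns=designs["C"].sample_names),
        }
        ms = ModuleSet(assignment=pd.Series(), eigengenes=eigengenes)
        cats, newick = categorize_timing(ms, designs)
        assert cats["ME1"] == "morning/day"  # 10:00 and 12:00 agree in window
        assert cats["ME2"] == "variable"  # 12:00 vs 02:00 disagree
        assert newick.endswith(";") and "ME1" in newick

    def test_planted_night_phase_categorized_in_all_series(self):
        from conftest import make_planted_series

        cs, truth, designs, _ = make_planted_series(
            n_series=3, n_times=12, spacing=2.0, module_genes=40, n_modules=2,
            flat_genes=40, dispersion=0.05, seed=21,
        )
        from dielmat.expression import cpm, filter_low_counts, rle_size_factors

        expr = {}
        for c in cs:
            counts, _ = filter_low_counts(c.counts)
            expr[c.series_id] = cpm(counts, rle_size_factors(counts)).values
        modules, _ = build_consensus_modules(expr)
        cats, _ = categorize_timing(
            modules, {d.series_id: d for d in designs}
        )
        # planted phases 0.0 (night) and 12.0 (day) must be recovered
        assert sorted(cats.values()) == ["evening/night", "morning/day"]
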