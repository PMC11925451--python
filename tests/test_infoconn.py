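"""Feature selection, decoding distances, and informational connectivity."""

import numpy as np
import pandas as pd
import pytest

from v2lamina import infoconn as ic
from v2lamina.exceptions import InputError


class TestL2Normalize:
    def test_three_four_five(self):
        assert np.allclose(ic.l2_normalize([3.0, 4.0]), [0.6, 0.8], atol=1e-12)

    def test_idempotent_on_unit_vectors(self, rng):
        u = ic.l2_normalize(rng.normal(size=7))
        assert np.allclose(ic.l2_normalize(u), u, atol=1e-12)

    def test_scale_invariant(self, rng):
        x = rng.normal(size=5)
        assert np.allclose(ic.l2_normalize(x), ic.l2_normalize(10.0 * x), atol=1e-12)

    def test_zero_vector_rejected(self):
        with pytest.raises(InputError):
            ic.l2_normalize(np.zeros(4))


class TestSelectFeatures:
    def test_standard_sizes(self, rng):
        vt = rng.normal(size=4000)
        dt = rng.normal(size=4000)
        fs = ic.select_features(vt, dt, top_frac=0.2, n_tail=200)
        assert fs.n_pool == 800
        assert fs.voxel_index.size == 400
        # every selected voxel is in the visual top 20%
        cut = np.sort(vt)[-800]
        assert np.all(vt[fs.voxel_index] >= cut)

    def test_all_positive_differential_takes_low_tail(self):
        vt = np.ones(100)
        dt = np.linspace(1.0, 2.0, 100)  # strictly positive
        fs = ic.select_features(vt, dt, top_frac=1.0, n_tail=10)
        chosen_dt = np.sort(dt[fs.voxel_index])
        # ten most-negative (= least positive) and ten largest
        assert np.allclose(chosen_dt[:10], dt[:10])
        assert np.allclose(chosen_dt[-10:], dt[-10:])

    def test_ties_broken_by_smaller_index(self):
        vt = np.ones(10)
        dt = np.ones(10)
        fs = ic.select_features(vt, dt, top_frac=0.6, n_tail=2)
        assert list(fs.voxel_index) == [0, 1, 2, 3]

    def test_pool_too_small_is_explicit(self):
        with pytest.raises(InputError, match="need"):
            ic.select_features(np.ones(100), np.ones(100), top_frac=0.2, n_tail=50)


def _toy_patterns(rng, n_runs=3, blocks_per_run=8, n_vox=6, signal=2.0):
    """Separable two-class block patterns with per-run metadata."""
    rows, metas = [], []
    template = np.zeros(n_vox)
    template[: n_vox // 2] = 1.0
    template[n_vox // 2 :] = -1.0
    for r in range(n_runs):
        for b in range(blocks_per_run):
            cond = "A" if (b + r) % 2 == 0 else "B"
            y = 1.0 if cond == "A" else -1.0
            rows.append(y * signal * template + rng.normal(scale=0.3, size=n_vox))
            metas.append({"run": r, "block": b, "condition": cond})
    blocks = pd.DataFrame(metas)
    stats = {
        r: (np.ones(n_vox), signal * template + rng.normal(scale=0.05, size=n_vox))
        for r in range(n_runs)
    }
    return np.array(rows), blocks, stats


class TestDecodeDistances:
    def test_separable_signs_match_labels(self, rng):
        patterns, blocks, stats = _toy_patterns(rng)
        ds = ic.decode_distances(
            patterns, blocks, stats, ("A", "B"), top_frac=1.0, n_tail=3
        )
        pred = np.sign(ds.distances)
        truth = np.where(ds.blocks["condition"] == "A", 1.0, -1.0)
        assert np.array_equal(pred, truth)

    def test_duplicated_voxels_leave_distances_unchanged(self, rng):
        """Feature duplication preserves the Gram matrix after L2
        normalisation, so the max-margin distances are identical."""
        patterns, blocks, stats = _toy_patterns(rng)
        a = ic.decode_distances(patterns, blocks, stats, ("A", "B"), top_frac=1.0, n_tail=3)
        dbl = np.hstack([patterns, patterns])
        stats2 = {r: (np.hstack([v, v]), np.hstack([d, d])) for r, (v, d) in stats.items()}
        b = ic.decode_distances(dbl, blocks, stats2, ("A", "B"), top_frac=1.0, n_tail=6)
        assert np.allclose(a.distances, b.distances, atol=1e-8)

    def test_shuffled_labels_give_chance_accuracy(self):
        """With labels randomly permuted within run, held-out accuracy sits
        at chance across many shuffles."""
        rng = np.random.default_rng(21)
        patterns, blocks, stats = _toy_patterns(rng, n_runs=4, signal=2.0)
        accs = []
        for _ in range(60):
            shuffled = blocks.copy()
            shuffled["condition"] = (
                shuffled.groupby("run")["condition"]
                .transform(lambda s: rng.permutation(s.to_numpy()))
            )
            ds = ic.decode_distances(
                patterns, shuffled, stats, ("A", "B"), top_frac=1.0, n_tail=3
            )
            truth = np.where(ds.blocks["condition"] == "A", 1.0, -1.0)
            accs.append((np.sign(ds.distances) == truth).mean())
        mean_acc = np.mean(accs)
        se = np.std(accs) / np.sqrt(len(accs))
        assert abs(mean_acc - 0.5) < max(3 * se, 0.06)

    def test_single_class_training_rejected(self, rng):
        patterns, blocks, stats = _toy_patterns(rng, n_runs=2)
        blocks.loc[blocks["run"] == 0, "condition"] = "A"
        with pytest.raises(InputError):
            ic.decode_distances(patterns, blocks, stats, ("A", "B"), top_frac=1.0, n_tail=3)


def _series(distances, blocks):
    return ic.DistanceSeries(np.asarray(distances, dtype=float), blocks.copy())


@pytest.fixture()
def fold_blocks():
    rows = []
    for fold, run in enumerate(range(4)):
        for b in range(8):
            rows.append(
                {
                    "run": run,
                    "block": b,
                    "condition": "A" if (b + run) % 2 == 0 else "B",
                    "fold": fold,
                }
            )
    return pd.DataFrame(rows)


class TestInformationalConnectivity:
    def test_identical_series_correlate_perfectly(self, fold_blocks, rng):
        d = rng.normal(size=len(fold_blocks))
        assert ic.informational_connectivity(
            _series(d, fold_blocks), _series(d, fold_blocks)
        ) == pytest.approx(1.0)

    def test_symmetric_in_arguments(self, fold_blocks, rng):
        a = _series(rng.normal(size=len(fold_blocks)), fold_blocks)
        b = _series(rng.normal(size=len(fold_blocks)), fold_blocks)
        assert ic.informational_connectivity(a, b) == pytest.approx(
            ic.informational_connectivity(b, a), abs=1e-12
        )

    def test_independent_noise_near_zero(self, fold_blocks):
        rng = np.random.default_rng(6)
        rs = [
            ic.informational_connectivity(
                _series(rng.normal(size=len(fold_blocks)), fold_blocks),
                _series(rng.normal(size=len(fold_blocks)), fold_blocks),
            )
            for _ in range(200)
        ]
        assert abs(np.mean(rs)) < 3 * np.std(rs) / np.sqrt(len(rs))

    def test_mismatched_blocks_rejected(self, fold_blocks, rng):
        a = _series(rng.normal(size=len(fold_blocks)), fold_blocks)
        other = fold_blocks.copy()
        other["condition"] = other["condition"].map({"A": "B", "B": "A"})
        with pytest.raises(InputError):
            ic.informational_connectivity(a, _series(rng.normal(size=len(other)), other))


class TestPathwayConventions:
    def test_layer_pairings(self):
        assert ic.PATHWAY_BINS["feedforward"] == ("superficial", "middle")
        assert ic.PATHWAY_BINS["feedback"] == ("deep", "deep")

    def test_matrix_uses_pairings(self, fold_blocks, rng):
        dist = {}
        for area in ("V1", "V2"):
            for b in ("deep", "middle", "superficial"):
                dist[("color", area, b)] = _series(
                    rng.normal(size=len(fold_blocks)), fold_blocks
                )
        out = ic.pathway_matrix(dist, pairs=(("V1", "V2"),))
        assert set(out["direction"]) == {"feedforward", "feedback"}
        assert len(out) == 2

    def test_missing_node_is_explicit(self, fold_blocks, rng):
        dist = {("color", "V1", "superficial"): _series(rng.normal(size=32), fold_blocks)}
        with pytest.raises(InputError, match="pathway"):
            ic.pathway_matrix(dist, pairs=(("V1", "V2"),))


class TestGroupInference:
    def test_hand_computed_t(self):
        rows = []
        for s, z in enumerate([0.5, 0.6, 0.7, 0.5, 0.6]):
            rows.append(
                {
                    "subject": s,
                    "contrast": "texture",
                    "lower": "V2",
                    "higher": "V4",
                    "direction": "feedback",
                    "z": z,
                }
            )
        out = ic.group_inference(pd.DataFrame(rows))
        assert out.loc[0, "t"] == pytest.approx(15.501152030920618, abs=1e-9)
        assert out.loc[0, "df"] == 4
        assert out.loc[0, "q"] == pytest.approx(out.loc[0, "p"])

    def test_fdr_spans_whole_family(self, rng):
        rows = []
        for s in range(6):
            for c in ("color", "texture"):
                for d in ("feedforward", "feedback"):
                    rows.append(
                        {
                            "subject": s,
                            "contrast": c,
                            "lower": "V1",
                            "higher": "V2",
                            "direction": d,
                            "z": rng.normal(),
                        }
                    )
        out = ic.group_inference(pd.DataFrame(rows))
        assert len(out) == 4
        from v2lamina import stats as vs

        assert np.allclose(np.sort(out["q"]), np.sort(vs.fdr_bh(out["p"].to_numpy())))
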