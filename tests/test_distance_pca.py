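import numpy as np
import pytest

from ascpanel import (
    AscPanelError,
    ConfigError,
    DistanceMatrix,
    PopulationAlleleFrequencies,
    PopulationPartition,
    default_config,
    distance_matrix,
    export_distance,
    pca,
    reynolds_distance,
    sample_genotypes,
    simulate_frequencies,
)
from conftest import make_dataset, random_dataset


def freqs_from_table(pop_freqs: dict, counts=20):
    pops = list(pop_freqs)
    f = np.array([pop_freqs[p] for p in pops], dtype=float)
    return PopulationAlleleFrequencies(
        population_ids=pops,
        freqs=f,
        counts=np.full(f.shape, counts, dtype=int),
    )


def parse_phylip_square(path):
    """Independent minimal PHYLIP square-distance parser."""
    lines = [l for l in open(path).read().splitlines() if l.strip()]
    n = int(lines[0])
    labels, rows = [], []
    for line in lines[1:]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1:]])
    assert len(rows) == n
    return labels, np.array(rows)


class TestReynolds:
    def test_identical_frequencies_zero(self):
        f = freqs_from_table({"A": [0.2, 0.5, 0.9], "B": [0.2, 0.5, 0.9]})
        assert reynolds_distance(f, "A", "B") == 0.0

    def test_opposite_fixation_single_locus_is_one(self):
        f = freqs_from_table({"A": [1.0], "B": [0.0]})
        assert reynolds_distance(f, "A", "B") == pytest.approx(1.0)

    def test_five_locus_hand_table_termwise(self):
        p1 = np.array([0.1, 0.4, 0.6, 0.9, 0.5])
        p2 = np.array([0.3, 0.4, 0.2, 0.5, 0.8])
        num = den = 0.0
        for a, b in zip(p1, p2):
            num += (a - b) ** 2
            den += 1 - a * b - (1 - a) * (1 - b)
        f = freqs_from_table({"A": p1, "B": p2})
        assert reynolds_distance(f, "A", "B") == pytest.approx(num / den, abs=1e-12)

    def test_loci_missing_in_one_population_excluded(self):
        f = freqs_from_table({"A": [0.2, np.nan, 0.8], "B": [0.2, 0.5, np.nan]})
        assert reynolds_distance(f, "A", "B") == 0.0  # only locus 0 shared

    def test_no_shared_loci_errors(self):
        f = freqs_from_table({"A": [np.nan, 0.5], "B": [0.5, np.nan]})
        with pytest.raises(AscPanelError, match="no shared loci"):
            reynolds_distance(f, "A", "B")

    def test_corrected_estimator_shrinks_sampling_noise(self, rng):
        """With identical true frequencies, the frequency-only estimator
        reports pure sampling noise; the small-sample-corrected one is ~0."""
        p = rng.uniform(0.2, 0.8, 3000)
        n = 15
        f = PopulationAlleleFrequencies(
            population_ids=["A", "B"],
            freqs=np.vstack(
                [rng.binomial(2 * n, p) / (2 * n), rng.binomial(2 * n, p) / (2 * n)]
            ),
            counts=np.full((2, 3000), n, dtype=int),
        )
        plain = reynolds_distance(f, "A", "B")
        corr = reynolds_distance(f, "A", "B", corrected=True)
        assert plain > 0.02            # noise floor ~ 1/(2n)
        assert abs(corr) < plain / 3   # correction removes most of it


class TestDistanceMatrix:
    def test_identical_populations_zero_matrix(self):
        f = freqs_from_table({"A": [0.3, 0.6], "B": [0.3, 0.6]})
        m = distance_matrix(f)
        np.testing.assert_allclose(m.matrix, 0.0)

    def test_permuting_population_order(self, rng):
        table = {p: rng.uniform(0.05, 0.95, 30) for p in "ABCD"}
        m1 = distance_matrix(freqs_from_table(table))
        rev = dict(reversed(list(table.items())))
        m2 = distance_matrix(freqs_from_table(rev))
        idx = [m2.labels.index(l) for l in m1.labels]
        np.testing.assert_allclose(m1.matrix, m2.matrix[np.ix_(idx, idx)], atol=1e-14)

    def test_symmetry_zero_diagonal_random(self, rng):
        for _ in range(5):
            table = {f"P{k}": rng.uniform(0, 1, 20) for k in range(4)}
            m = distance_matrix(freqs_from_table(table))
            np.testing.assert_allclose(m.matrix, m.matrix.T)
            np.testing.assert_allclose(np.diag(m.matrix), 0.0)
            assert np.isfinite(m.matrix).all()

    def test_distance_grows_with_simulated_divergence(self):
        """Star layout: populations at increasing divergence from the root
        must show increasing Reynolds distance from a near-root population."""
        from ascpanel import PopulationSpec, SimulationConfig
        cfg = SimulationConfig(
            seed=7, n_loci=4000, missing_rate=0.0,
            clades={"c0": 0.005, "c1": 0.05, "c2": 0.15, "c3": 0.30},
            populations=[PopulationSpec(f"P{k}", f"c{k}", 0.0, 25) for k in range(4)],
            discovery_populations=["P0"],
        )
        truth = simulate_frequencies(cfg)
        ds = sample_genotypes(truth, cfg)
        part = PopulationPartition.from_dataset(ds)
        f = PopulationAlleleFrequencies.from_dataset(ds, part)
        d = [reynolds_distance(f, "P0", f"P{k}") for k in (1, 2, 3)]
        assert d[0] < d[1] < d[2]


class TestExport:
    def test_phylip_roundtrip(self, tmp_path, rng):
        table = {f"Pop{k}": rng.uniform(0.1, 0.9, 25) for k in range(3)}
        m = distance_matrix(freqs_from_table(table))
        path = tmp_path / "d.phy"
        export_distance(m, path, format="phylip")
        labels, back = parse_phylip_square(path)
        assert labels == m.labels
        np.testing.assert_allclose(back, m.matrix, atol=5e-7)

    def test_nexus_structure(self, tmp_path):
        m = DistanceMatrix(labels=["A", "B", "C"], matrix=np.zeros((3, 3)))
        path = tmp_path / "d.nex"
        export_distance(m, path, format="nexus")
        text = path.read_text()
        assert text.startswith("#NEXUS")
        assert "BEGIN TAXA;" in text and "BEGIN DISTANCES;" in text
        assert "NTAX=3" in text and "TAXLABELS A B C;" in text

    def test_label_sanitization_and_collisions(self, tmp_path):
        m = DistanceMatrix(labels=["a b", "a_b"], matrix=np.zeros((2, 2)))
        with pytest.raises(ConfigError, match="collision"):
            export_distance(m, tmp_path / "x.phy", format="phylip")
        m2 = DistanceMatrix(labels=["", "ok"], matrix=np.zeros((2, 2)))
        with pytest.raises(ConfigError, match="empty"):
            export_distance(m2, tmp_path / "y.phy", format="phylip")


class TestPCA:
    def test_duplicate_samples_identical_coordinates(self, rng):
        ds = random_dataset(rng, 8, 20, missing_rate=0.0)
        g = np.vstack([ds.genotypes, ds.genotypes[:1]])
        dup = make_dataset(g, chromosomes=list(ds.loci["chromosome"]),
                           positions=list(ds.loci["position_bp"]))
        res = pca(dup, np.arange(20), n_components=3)
        pcs = res.scores[[c for c in res.scores if c.startswith("PC")]].to_numpy()
        np.testing.assert_allclose(pcs[0], pcs[-1], atol=1e-9)

    def test_two_clades_separate_on_pc1(self, rng):
        p1, p2 = np.full(40, 0.05), np.full(40, 0.95)
        g = np.vstack(
            [rng.binomial(2, p1, (10, 40)), rng.binomial(2, p2, (10, 40))]
        ).astype(np.int8)
        ds = make_dataset(g, populations=["A"] * 10 + ["B"] * 10)
        res = pca(ds, np.arange(40), n_components=4)
        pc1 = res.scores["PC1"].to_numpy()
        assert (pc1[:10].max() < pc1[10:].min()) or (pc1[:10].min() > pc1[10:].max())
        assert res.variance_explained[0] == max(res.variance_explained)

    def test_matches_direct_svd_on_fixture(self, rng):
        """Scores reproduce the SVD of the centred/scaled matrix, built
        independently here, on a 6 x 10 complete-data fixture."""
        ds = random_dataset(rng, 6, 10, missing_rate=0.0)
        g = ds.genotypes.astype(float)
        p = g.mean(axis=0) / 2
        x = (g - 2 * p) / np.sqrt(2 * p * (1 - p))
        u, s, vt = np.linalg.svd(x, full_matrices=False)
        res = pca(ds, np.arange(10), n_components=5)
        k = len(res.eigenvalues)
        got = res.scores[[f"PC{c+1}" for c in range(k)]].to_numpy()
        want = u[:, :k] * s[:k]
        for c in range(k):   # sign-insensitive column comparison
            assert np.allclose(got[:, c], want[:, c], atol=1e-9) or np.allclose(
                got[:, c], -want[:, c], atol=1e-9
            )
        np.testing.assert_allclose(
            res.variance_explained[:k], (s**2 / (s**2).sum())[:k], atol=1e-12
        )

    def test_variance_proportions_monotone_and_scores_orthogonal(self, rng):
        ds = random_dataset(rng, 15, 30, missing_rate=0.1)
        res = pca(ds, np.arange(30), n_components=6)
        v = res.variance_explained
        assert np.all(np.diff(v) <= 1e-12) and np.all(v >= 0) and np.all(v <= 1)
        pcs = res.scores[[f"PC{c+1}" for c in range(len(v))]].to_numpy()
        gram = pcs.T @ pcs
        np.testing.assert_allclose(gram - np.diag(np.diag(gram)), 0.0, atol=1e-8)

    def test_zero_variance_panel_rejected(self):
        ds = make_dataset(np.full((4, 3), 2, dtype=np.int8))
        with pytest.raises(AscPanelError, match="zero-variance"):
            pca(ds, np.arange(3))
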