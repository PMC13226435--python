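import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import silhouette_score

from chemchron import chem, embedding, scaffolds


def fp(smiles, **kw):
    return embedding.circular_fingerprint(chem.parse_smiles(smiles), **kw)


def family_frameworks(ring_size, n=8):
    """n distinct all-carbon frameworks built from chains of k rings of one size."""
    out = []
    for k in range(1, n + 1):
        parts = []
        for i in range(k):
            digit = str((i % 2) + 1)
            parts.append("C" + digit + "C" * (ring_size - 1) + digit)
        fw = scaffolds.generic_framework(chem.canonicalize("".join(parts)))
        out.append(fw.canonical_smiles)
    assert len(set(out)) == n
    return out


class TestCircularFingerprint:
    def test_spelling_invariance(self):
        assert np.array_equal(fp("c1ccccc1"), fp("c1ccccc1"))
        assert np.array_equal(fp("C1=CC=CC=C1"), fp("c1ccccc1"))

    def test_atom_order_invariance_random_renumberings(self, rng):
        from rdkit import Chem

        mol = chem.parse_smiles("O=C(Nc1ccc(F)cc1)c1ccccc1")
        ref = embedding.circular_fingerprint(mol)
        for _ in range(20):
            order = list(rng.permutation(mol.GetNumAtoms()))
            renum = Chem.RenumberAtoms(mol, [int(i) for i in order])
            renum = chem.parse_smiles(Chem.MolToSmiles(renum, canonical=False))
            assert np.array_equal(embedding.circular_fingerprint(renum), ref)

    def test_nonempty_and_length(self):
        v = fp("c1ccccc1", n_bits=512)
        assert v.shape == (512,) and v.sum() >= 1

    def test_generic_frameworks_of_benzene_and_cyclohexane_identical(self):
        fw1 = scaffolds.framework_from_smiles("c1ccccc1").canonical_smiles
        fw2 = scaffolds.framework_from_smiles("C1CCCCC1").canonical_smiles
        assert fw1 == fw2
        assert np.array_equal(fp(fw1), fp(fw2))

    def test_empty_molecule_rejected(self):
        with pytest.raises(ValueError):
            embedding.circular_fingerprint(None)


class TestReduceDimensions:
    def test_duplicate_rows_coincide(self):
        keys = ["C1CCCCC1", "C1CCCCC1", "C1CCCC1", "C1CCCCCC1"]
        m = embedding.fingerprint_matrix(keys)
        coords = embedding.reduce_dimensions(m, n_components=3)
        assert np.allclose(coords[0], coords[1])

    def test_variances_non_increasing(self):
        keys = family_frameworks(5) + family_frameworks(6) + family_frameworks(7)
        m = embedding.fingerprint_matrix(keys)
        coords = embedding.reduce_dimensions(m, n_components=5)
        var = coords.var(axis=0)
        assert all(a >= b - 1e-12 for a, b in zip(var, var[1:]))

    def test_component_clamp_warns(self):
        m = embedding.fingerprint_matrix(["C1CCCCC1", "C1CCCC1", "C1CCCCCC1"])
        with pytest.warns(UserWarning, match="reduced"):
            coords = embedding.reduce_dimensions(m, n_components=50)
        assert coords.shape == (3, 3)


class TestEmbed2d:
    def test_deterministic_under_seed(self):
        keys = family_frameworks(5) + family_frameworks(6)
        m = embedding.fingerprint_matrix(keys)
        red = embedding.reduce_dimensions(m, n_components=5)
        a = embedding.embed_2d(red, perplexity=3, seed=42)
        b = embedding.embed_2d(red, perplexity=3, seed=42)
        assert np.array_equal(a, b)

    def test_row_count_preserved(self):
        keys = family_frameworks(6)
        red = embedding.reduce_dimensions(embedding.fingerprint_matrix(keys), 4)
        assert embedding.embed_2d(red, perplexity=2, seed=0).shape == (len(keys), 2)

    def test_perplexity_too_large_rejected(self):
        red = np.eye(4)
        with pytest.raises(ValueError, match="perplexity"):
            embedding.embed_2d(red, perplexity=10, seed=0)

    def test_family_separation_silhouette(self):
        """Ring-size families (5/6/7-membered, decorated) separate in 2D."""
        fams = [family_frameworks(s, n=10) for s in (5, 6, 7)]
        keys = [k for fam in fams for k in fam]
        labels = [i for i, fam in enumerate(fams) for _ in fam]
        m = embedding.fingerprint_matrix(keys)
        red = embedding.reduce_dimensions(m, n_components=min(10, len(keys)))
        coords = embedding.embed_2d(red, perplexity=5, seed=1)
        assert silhouette_score(coords, labels) > 0

    def test_nearest_neighbors_share_family(self):
        fams = [family_frameworks(s, n=10) for s in (5, 6, 7)]
        keys = [k for fam in fams for k in fam]
        labels = np.array([i for i, fam in enumerate(fams) for _ in fam])
        m = embedding.fingerprint_matrix(keys)
        red = embedding.reduce_dimensions(m, n_components=min(10, len(keys)))
        coords = embedding.embed_2d(red, perplexity=5, seed=1)
        d = ((coords[:, None, :] - coords[None, :, :]) ** 2).sum(-1)
        np.fill_diagonal(d, np.inf)
        hits = 0
        for i in range(len(keys)):
            nn = np.argsort(d[i])[:3]
            if (labels[nn] == labels[i]).sum() >= 2:
                hits += 1
        assert hits / len(keys) > 0.5


class TestSnapshotSeries:
    def make_data(self):
        rows = []
        for i, fam_year in enumerate([(5, 1985), (6, 1995), (7, 2015)]):
            size, year = fam_year
            for j, fw in enumerate(family_frameworks(size, n=6)):
                rows.append({"framework": fw, "year": year + j})
        return pd.DataFrame(rows)

    def test_composition_identity_single_era(self):
        data = self.make_data()
        res = embedding.snapshot_series(data, [2024], seed=3, n_components=10, perplexity=4)
        assert 2024 in res
        r = res[2024]
        counts = data[data.framework.astype(bool)]["framework"].value_counts().sort_index()
        m = embedding.fingerprint_matrix(list(counts.index))
        red = embedding.reduce_dimensions(m, n_components=10)
        manual = embedding.embed_2d(red, perplexity=r.params["perplexity"], seed=3)
        assert r.keys == list(counts.index)
        assert np.array_equal(r.coords, manual)

    def test_weights_sum_to_era_molecule_count(self):
        data = self.make_data()
        res = embedding.snapshot_series(data, [1990, 2024], seed=0, n_components=5, perplexity=3)
        for cut, r in res.items():
            n_era = int(((data["year"] <= cut) & data["framework"].astype(bool)).sum())
            assert int(r.weights.sum()) == n_era

    def test_framework_absent_before_first_appearance(self):
        data = self.make_data()
        res = embedding.snapshot_series(data, [1990, 2024], seed=0, n_components=5, perplexity=3)
        late = set(data.loc[data["year"] > 1990, "framework"]) - set(
            data.loc[data["year"] <= 1990, "framework"]
        )
        assert late
        assert not late & set(res[1990].keys)
        assert late <= set(res[2024].keys)

    def test_small_era_skipped_with_warning(self):
        data = pd.DataFrame({"framework": ["C1CCCCC1", "C1CCCC1"], "year": [1980, 1981]})
        with pytest.warns(UserWarning, match="skipped"):
            res = embedding.snapshot_series(data, [1985], seed=0)
        assert res == {}
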