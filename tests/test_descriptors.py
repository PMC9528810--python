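import itertools

import numpy as np
import pandas as pd
import pytest
from rdkit import Chem

from snarpred import descriptors
from snarpred.descriptors import (
    FeatureSetSpec,
    assemble,
    attach_solvent_pcs,
    feature_set_columns,
    morgan_difference_fingerprint,
    pf2_expand,
    ts_columns,
)


class TestFeatureSets:
    def test_counts(self):
        assert len(feature_set_columns("X_full")) == 34
        assert len(feature_set_columns("X_small")) == 12

    def test_inclusion_lattice(self):
        full = set(feature_set_columns("X_full"))
        no_ts = set(feature_set_columns("X_noTS"))
        trad = set(feature_set_columns("X_trad"))
        surf = set(feature_set_columns("X_surf"))
        assert trad < no_ts < full
        assert surf < no_ts

    def test_no_ts_excludes_ts_columns(self):
        no_ts = set(feature_set_columns("X_noTS"))
        assert not (no_ts & set(ts_columns()))
        assert "dG_dft" not in no_ts

    def test_small_has_dft_as_only_ts_column(self):
        small = set(feature_set_columns("X_small"))
        assert small & set(ts_columns()) == {"dG_dft"}

    def test_trad_removes_surface_descriptors(self):
        no_ts = set(feature_set_columns("X_noTS"))
        trad = set(feature_set_columns("X_trad"))
        assert no_ts - trad == {"Vs_C", "Vs_N", "Is_min_N", "Es_min_C", "P_int"}

    def test_unknown_set_errors(self):
        with pytest.raises(KeyError):
            feature_set_columns("X_bogus")

    def test_custom_requires_columns(self):
        with pytest.raises(ValueError):
            FeatureSetSpec(name="custom")

    def test_morgan_spec_is_fingerprint_plus_solvent(self):
        spec = FeatureSetSpec(name="X_Morgan")
        assert spec.include_fingerprint
        assert spec.columns == ["PC1", "PC2", "PC3", "PC4", "PC5"]

    def test_combined_spec_extends_full(self):
        spec = FeatureSetSpec(name="X_combined")
        assert spec.include_fingerprint
        assert spec.columns == feature_set_columns("X_full")


class TestAssemble:
    def test_shapes_and_order(self, small_dataset):
        X, y, cols = assemble(
            small_dataset.reaction_table,
            small_dataset.descriptor_table,
            FeatureSetSpec(name="X_full"),
        )
        assert X.shape == (120, 34)
        assert cols == feature_set_columns("X_full")
        np.testing.assert_allclose(y, small_dataset.reaction_table["dG_exp_kcal"])

    def test_small_set_width(self, small_dataset):
        X, _, _ = assemble(
            small_dataset.reaction_table,
            small_dataset.descriptor_table,
            FeatureSetSpec(name="X_small"),
        )
        assert X.shape[1] == 12

    def test_unreferenced_column_can_be_dropped(self, small_dataset):
        pruned = small_dataset.descriptor_table.drop(columns=["q_C_TS"])
        X1, _, _ = assemble(
            small_dataset.reaction_table, pruned, FeatureSetSpec(name="X_noTS")
        )
        X2, _, _ = assemble(
            small_dataset.reaction_table,
            small_dataset.descriptor_table,
            FeatureSetSpec(name="X_noTS"),
        )
        np.testing.assert_array_equal(X1, X2)

    def test_missing_column_lists_offenders(self, small_dataset):
        pruned = small_dataset.descriptor_table.drop(columns=["dG_dft", "q_C"])
        with pytest.raises(ValueError) as err:
            assemble(small_dataset.reaction_table, pruned, FeatureSetSpec(name="X_full"))
        assert "dG_dft" in str(err.value) and "q_C" in str(err.value)

    def test_unmatched_rxn_id_errors(self, small_dataset):
        table = small_dataset.reaction_table.copy()
        table.loc[0, "rxn_id"] = "MISSING"
        with pytest.raises(ValueError, match="MISSING"):
            assemble(table, small_dataset.descriptor_table, FeatureSetSpec(name="X_full"))

    def test_assemble_morgan_spec_end_to_end(self):
        from snarpred import synthetic

        ds = synthetic.generate(
            synthetic.GeneratorConfig(n_samples=12, seed=0, with_smiles=True)
        )
        spec = FeatureSetSpec(name="X_Morgan", fingerprint_width=256)
        X, y, cols = assemble(ds.reaction_table, ds.descriptor_table, spec)
        assert X.shape == (12, 5 + 256)
        assert cols[:5] == ["PC1", "PC2", "PC3", "PC4", "PC5"]

    def test_row_order_follows_reaction_table(self, small_dataset):
        reversed_table = small_dataset.reaction_table.iloc[::-1].reset_index(drop=True)
        X_fwd, _, _ = assemble(
            small_dataset.reaction_table,
            small_dataset.descriptor_table,
            FeatureSetSpec(name="X_full"),
        )
        X_rev, _, _ = assemble(
            reversed_table, small_dataset.descriptor_table, FeatureSetSpec(name="X_full")
        )
        np.testing.assert_array_equal(X_rev, X_fwd[::-1])


class TestPf2:
    def test_d2_layout(self):
        out = pf2_expand(np.array([[2.0, 3.0]]))
        np.testing.assert_allclose(out, [[2.0, 3.0, 4.0, 6.0, 9.0]])

    def test_d1(self):
        np.testing.assert_allclose(pf2_expand(np.array([[3.0]])), [[3.0, 9.0]])

    @pytest.mark.parametrize("d,expected", [(2, 5), (5, 20), (34, 629)])
    def test_width(self, d, expected):
        out = pf2_expand(np.ones((2, d)))
        assert out.shape[1] == expected

    def test_commutes_with_row_permutation(self, rng):
        X = rng.normal(size=(10, 4))
        perm = rng.permutation(10)
        np.testing.assert_allclose(pf2_expand(X)[perm], pf2_expand(X[perm]))

    def test_contains_original_columns(self, rng):
        X = rng.normal(size=(6, 3))
        np.testing.assert_allclose(pf2_expand(X)[:, :3], X)

    def test_column_names_match_width(self):
        names = descriptors.pf2_column_names(["a", "b", "c"])
        assert len(names) == 3 + 6
        assert names[:3] == ["a", "b", "c"]
        assert "a*b" in names and "a^2" in names


def _enumerate_environments(smiles, radius):
    """Independent oracle: enumerate circular environments up to ``radius``
    by explicit bond-set construction.  Environments at radius >= 1 covering
    a bond set already produced are deduplicated (the Morgan convention);
    every atom contributes a radius-0 environment.  Returns the list of
    counted (radius, bond frozenset) environments."""
    mol = Chem.MolFromSmiles(smiles)
    seen = set()
    counted = []
    for r in range(radius + 1):
        for atom in mol.GetAtoms():
            if r == 0:
                counted.append((0, frozenset([("atom", atom.GetIdx())])))
                continue
            env = Chem.FindAtomEnvironmentOfRadiusN(mol, r, atom.GetIdx())
            if not env:
                continue
            key = frozenset(env)
            if key in seen:
                continue
            seen.add(key)
            counted.append((r, key))
    return counted


class TestMorganFingerprint:
    def test_identity_reaction_zero(self):
        vec = morgan_difference_fingerprint("c1ccccc1>>c1ccccc1", radius=2)
        assert not vec.any()

    def test_antisymmetry(self):
        fwd = morgan_difference_fingerprint(
            "c1ccccc1F.[O-]C>>c1ccccc1OC.[F-]", radius=3
        )
        rev = morgan_difference_fingerprint(
            "c1ccccc1OC.[F-]>>c1ccccc1F.[O-]C", radius=3
        )
        np.testing.assert_array_equal(fwd, -rev)

    @pytest.mark.parametrize("radius", [1, 2])
    def test_total_count_matches_enumeration_oracle(self, radius):
        # sum over the difference vector = total product environments minus
        # total reactant environments, checked against explicit bond-set
        # enumeration (assumes no cross-environment hash collisions at this size)
        rxn = "c1ccccc1F.[O-]C>>c1ccccc1OC.[F-]"
        vec = morgan_difference_fingerprint(rxn, radius=radius, width=4096)
        reactants, _, products = rxn.split(">")

        def total(side):
            return sum(
                len(_enumerate_environments(s, radius)) for s in side.split(".")
            )

        assert vec.sum() == total(products) - total(reactants)

    def test_changed_environments_only(self):
        # unchanged benzene ring far from the substitution site cancels:
        # adding the same spectator molecule to both sides changes nothing
        base = morgan_difference_fingerprint("c1ccccc1F.[O-]C>>c1ccccc1OC.[F-]")
        spect = morgan_difference_fingerprint(
            "c1ccccc1F.[O-]C.CCCC>>c1ccccc1OC.[F-].CCCC"
        )
        np.testing.assert_array_equal(base, spect)

    def test_agents_ignored(self):
        with_agent = morgan_difference_fingerprint("CCF>O>CCO")
        without = morgan_difference_fingerprint("CCF>>CCO")
        np.testing.assert_array_equal(with_agent, without)

    def test_unparseable_raises_with_string(self):
        with pytest.raises(ValueError, match="xyz123"):
            morgan_difference_fingerprint("xyz123>>CC")

    def test_missing_side_raises(self):
        with pytest.raises(ValueError):
            morgan_difference_fingerprint(">>CC")

    def test_radius_monotonicity(self):
        # environments counted at radius r are a subset of those at r+1
        mol = "Fc1ccc(cc1)[N+](=O)[O-]"
        for r in range(3):
            small = _enumerate_environments(mol, r)
            large = _enumerate_environments(mol, r + 1)
            assert set(small) <= set(large)


class TestSolventPcs:
    def test_appends_five_columns(self, small_dataset, rng):
        fp = rng.normal(size=(len(small_dataset.reaction_table), 16))
        out = attach_solvent_pcs(
            fp, small_dataset.solvent_table, small_dataset.reaction_table
        )
        assert out.shape[1] == 21

    def test_same_solvent_same_block(self, small_dataset):
        table = small_dataset.reaction_table.copy()
        table["solvent"] = "water"
        out = attach_solvent_pcs(
            np.zeros((len(table), 2)), small_dataset.solvent_table, table
        )
        assert (out[:, 2:] == out[0, 2:]).all()

    def test_reproduces_table_rows(self, small_dataset):
        out = attach_solvent_pcs(
            np.zeros((len(small_dataset.reaction_table), 1)),
            small_dataset.solvent_table,
            small_dataset.reaction_table,
        )
        lookup = small_dataset.solvent_table.set_index("solvent")
        for i, solvent in enumerate(small_dataset.reaction_table["solvent"]):
            np.testing.assert_allclose(
                out[i, 1:], lookup.loc[solvent, ["PC1", "PC2", "PC3", "PC4", "PC5"]]
            )

    def test_unknown_solvent_named(self, small_dataset):
        table = small_dataset.reaction_table.copy()
        table.loc[3, "solvent"] = "brine"
        with pytest.raises(ValueError, match="brine"):
            attach_solvent_pcs(
                np.zeros((len(table), 1)), small_dataset.solvent_table, table
            )
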