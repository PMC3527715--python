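"""Best-subset CV selection, logistic refit, counting and cutoffs."""

import numpy as np
import pytest

from phylopc.core_io import load_table1_fixture, read_newick
from phylopc.clade_concordance import (
    SubsetCVConfig,
    best_subset_cv,
    build_association_table,
    clade_membership,
    count_components,
    refit_logistic,
    select_components,
)
from phylopc.structure_pca import PCAResult


def scores_from(matrix: np.ndarray, ids=None) -> PCAResult:
    n, k = matrix.shape
    return PCAResult(
        scores=np.asarray(matrix, dtype=float),
        eigenvalues=np.linspace(k, 1, k),
        n_snps_used=1000,
        sample_ids=ids or [f"S{i}" for i in range(n)],
    )


class TestCladeMembership:
    TREE = "(((A,B,C,D,E)X11,(F,G,H,I,J)X12)X1,((K,L,M,N,P)X21,Q)X2,O);"

    def test_counts_and_nesting(self):
        t = read_newick(self.TREE)
        samples = list("ABCDEFGHIJKLMN") + ["P", "Q", "O"]
        top = clade_membership(t, "X1", samples)
        sub = clade_membership(t, "X11", samples)
        assert int(sub.sum()) == 5
        assert int(top.sum()) == 10
        assert np.all(sub <= top)  # nested clade implies membership

    def test_unknown_clade_and_sample_errors(self):
        t = read_newick(self.TREE)
        with pytest.raises(KeyError):
            clade_membership(t, "X99", list("AB"))
        with pytest.raises(ValueError, match="not in tree"):
            clade_membership(t, "X1", ["A", "ZZ"])


class TestBestSubsetCV:
    def cfg(self, **kw):
        base = dict(n_folds=5, n_replicates=25, max_model_size=4,
                    candidate_components=[1, 2, 3, 4, 5, 6], seed=0)
        base.update(kw)
        return SubsetCVConfig(**base)

    def test_constructed_separation_selects_informative_component(self, rng):
        # membership determined by component 1 alone: the procedure must
        # always keep component 1 and at most one incidental companion
        for s in range(5):
            r = np.random.default_rng(100 + s)
            X = r.normal(size=(200, 6))
            y = (X[:, 0] > 0).astype(float)
            sel = best_subset_cv(y, scores_from(X), self.cfg(seed=s))
            assert 1 in sel
            assert len(sel) <= 2

    def test_null_labels_select_nothing(self):
        hits = 0
        for s in range(5):
            r = np.random.default_rng(200 + s)
            X = r.normal(size=(150, 6))
            y = r.permutation([0] * 75 + [1] * 75).astype(float)
            sel = best_subset_cv(y, scores_from(X),
                                 self.cfg(seed=s, band="sd"))
            hits += sel == []
        assert hits >= 3

    def test_zero_model_size_forces_empty(self, rng):
        X = rng.normal(size=(60, 6))
        y = (X[:, 0] > 0).astype(float)
        sel = best_subset_cv(y, scores_from(X), self.cfg(max_model_size=0))
        assert sel == []

    def test_single_class_membership_rejected(self, rng):
        X = rng.normal(size=(40, 6))
        with pytest.raises(ValueError, match="degenerate"):
            best_subset_cv(np.ones(40), scores_from(X), self.cfg())

    def test_deterministic_given_seed(self, rng):
        X = rng.normal(size=(80, 6))
        y = (X[:, 1] - 0.5 * X[:, 2] > 0).astype(float)
        a = best_subset_cv(y, scores_from(X), self.cfg(seed=7))
        b = best_subset_cv(y, scores_from(X), self.cfg(seed=7))
        assert a == b


class TestRefitLogistic:
    def test_parameter_recovery(self):
        r = np.random.default_rng(42)
        X = r.normal(size=(5000, 3))
        logit = 0.5 * X[:, 0]
        y = (r.random(5000) < 1 / (1 + np.exp(-logit))).astype(float)
        cells = refit_logistic(y, scores_from(X), [1])
        assert cells[1].beta == pytest.approx(0.5, abs=0.1)
        assert cells[1].p < 1e-10
        assert not cells[1].separation

    def test_null_pvalues_roughly_uniform(self):
        pvals = []
        for s in range(40):
            r = np.random.default_rng(300 + s)
            X = r.normal(size=(120, 2))
            y = r.integers(0, 2, size=120).astype(float)
            pvals.append(refit_logistic(y, scores_from(X), [2])[2].p)
        pvals = np.array(pvals)
        assert 0.2 < (pvals < 0.5).mean() < 0.8
        assert (pvals < 0.05).sum() <= 7

    def test_complete_separation_flagged_with_finite_estimate(self):
        X = np.linspace(-2, 2, 40)[:, None]
        y = (X[:, 0] > 0).astype(float)
        cells = refit_logistic(y, scores_from(X), [1])
        assert cells[1].separation
        assert np.isfinite(cells[1].beta) and cells[1].se > 0

    def test_empty_selection_rejected(self, rng):
        with pytest.raises(ValueError):
            refit_logistic(np.array([0.0, 1.0]),
                           scores_from(rng.normal(size=(2, 2))), [])


class TestTableAndSelection:
    def test_published_counts(self):
        counts = count_components(load_table1_fixture())
        assert counts[2] == 7
        assert counts[34] == 6
        assert counts[1] == 9

    def test_published_cutoff_selections(self):
        counts = count_components(load_table1_fixture())
        assert select_components(counts, 5) == [1, 2, 33, 34]
        assert select_components(counts, 3) == [1, 2, 4, 5, 33, 34, 35]

    def test_selection_monotone_in_cutoff(self):
        counts = count_components(load_table1_fixture())
        previous = None
        for cutoff in range(1, 12):
            sel = set(select_components(counts, cutoff))
            if previous is not None:
                assert sel <= previous
            previous = sel
        assert select_components(counts, 99) == []
        with pytest.raises(ValueError):
            select_components(counts, 0)

    def test_end_to_end_synthetic_clade_selects_structure_component(self):
        r = np.random.default_rng(9)
        n = 60
        ids = [f"S{i}" for i in range(n)]
        X = r.normal(size=(n, 4))
        members = ids[:20]
        X[:20, 0] += 4.0  # clade loads on component 1
        tree = read_newick(
            "((" + ",".join(members) + ")C1,"
            + ",".join(ids[20:]) + ");"
        )
        cfg = SubsetCVConfig(n_folds=5, n_replicates=20, max_model_size=3,
                             candidate_components=[1, 2, 3, 4], seed=1)
        table = build_association_table(tree, scores_from(X, ids), cfg)
        assert ("C1", 1) in table.cells
        counts = count_components(table)
        assert counts[1] == 1

    def test_zero_clade_tree_gives_empty_table(self, rng):
        tree = read_newick("(A,B,C,D);")
        X = rng.normal(size=(4, 3))
        cfg = SubsetCVConfig(n_folds=2, n_replicates=5, max_model_size=2,
                             candidate_components=[1, 2, 3], seed=0)
        table = build_association_table(
            tree, scores_from(X, list("ABCD")), cfg
        )
        assert table.cells == {}

    def test_tsv_layout_clades_as_columns(self):
        text = load_table1_fixture().to_tsv()
        header = text.splitlines()[0].split("\t")
        assert header[0] == "component"
        assert header[1:] == load_table1_fixture().clades
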