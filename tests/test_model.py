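"""Core model tests: ANOVA covariance partition, contrasts, the generalized
eigensolve, partial-table fits and projection."""

import numpy as np
import pytest

from flda.datatypes import ExpressionMatrix, FactorDesign
from flda.model import (
    FLDA,
    FLDAConfig,
    build_contrast,
    compute_decomposition,
    fit_flda,
    fit_flda_partial,
    project,
    solve_component,
)

from conftest import make_design, make_expression


def brute_force_decomposition(X, labels, levels_i, levels_j):
    """Literal transcription of the two-way ANOVA covariance partition:
    independent of the implementation, loops and outer products only."""
    g = X.shape[0]
    a, b = len(levels_i), len(levels_j)
    m = {}
    n = {}
    for i in levels_i:
        for j in levels_j:
            cols = [k for k, lab in enumerate(labels) if lab == (i, j)]
            n[(i, j)] = len(cols)
            m[(i, j)] = X[:, cols].mean(axis=1)
    m_i = {i: sum(m[(i, j)] for j in levels_j) / b for i in levels_i}
    m_j = {j: sum(m[(i, j)] for i in levels_i) / a for j in levels_j}
    m_all = sum(m[(i, j)] for i in levels_i for j in levels_j) / (a * b)

    MA = np.zeros((g, g))
    for i in levels_i:
        d = (m_i[i] - m_all)[:, None]
        MA += d @ d.T
    MA /= a - 1
    MB = np.zeros((g, g))
    for j in levels_j:
        d = (m_j[j] - m_all)[:, None]
        MB += d @ d.T
    MB /= b - 1
    MAB = np.zeros((g, g))
    for i in levels_i:
        for j in levels_j:
            d = (m[(i, j)] - m_i[i] - m_j[j] + m_all)[:, None]
            MAB += d @ d.T
    MAB /= (a - 1) * (b - 1)
    N = len(labels)
    Me = np.zeros((g, g))
    for i in levels_i:
        for j in levels_j:
            cols = [k for k, lab in enumerate(labels) if lab == (i, j)]
            inner = np.zeros((g, g))
            for k in cols:
                d = (X[:, k] - m[(i, j)])[:, None]
                inner += d @ d.T
            Me += inner / n[(i, j)]
    Me /= N - a * b
    return MA, MB, MAB, Me


# ------------------------------------------------------------- decomposition


def test_decomposition_matches_brute_force_transcription(rng):
    X = rng.normal(size=(2, 8)).round(2)
    fd = make_design(2, 2, 2)
    em = make_expression(X)
    cd = compute_decomposition(em, fd)
    MA, MB, MAB, Me = brute_force_decomposition(
        X, fd.labels, ["i1", "i2"], ["j1", "j2"]
    )
    np.testing.assert_allclose(cd.M_A, MA, atol=1e-12)
    np.testing.assert_allclose(cd.M_B, MB, atol=1e-12)
    np.testing.assert_allclose(cd.M_AB, MAB, atol=1e-12)
    np.testing.assert_allclose(cd.M_e, Me, atol=1e-12)
    np.testing.assert_allclose(np.diag(cd.M_e), cd.M_e_diag, atol=1e-12)


def test_decomposition_unbalanced_counts_match_brute_force(rng):
    # unbalanced n_ij exercise the unweighted marginal means and 1/n_ij weights
    counts = {("i1", "j1"): 3, ("i1", "j2"): 5, ("i2", "j1"): 2, ("i2", "j2"): 4}
    labels = [t for t, c in counts.items() for _ in range(c)]
    fd = FactorDesign([f"c{k}" for k in range(len(labels))], ["fi", "fj"], labels)
    X = rng.normal(size=(3, len(labels)))
    em = make_expression(X)
    cd = compute_decomposition(em, fd)
    MA, MB, MAB, Me = brute_force_decomposition(X, labels, ["i1", "i2"], ["j1", "j2"])
    np.testing.assert_allclose(cd.M_A, MA, atol=1e-12)
    np.testing.assert_allclose(cd.M_B, MB, atol=1e-12)
    np.testing.assert_allclose(cd.M_AB, MAB, atol=1e-12)
    np.testing.assert_allclose(cd.M_e, Me, atol=1e-12)


def test_identical_cells_give_zero_matrices():
    fd = make_design(2, 2, 2)
    em = make_expression(np.ones((3, 8)))
    cd = compute_decomposition(em, fd)
    for M in (cd.M_A, cd.M_B, cd.M_AB, cd.M_e):
        np.testing.assert_allclose(M, 0, atol=1e-14)


def test_zero_within_noise_gives_zero_residual(rng):
    fd = make_design(2, 2, 3)
    type_means = rng.normal(size=(4, 2))
    X = np.repeat(type_means, 3, axis=0).T  # every cell equals its type mean
    cd = compute_decomposition(make_expression(X), fd)
    np.testing.assert_allclose(cd.M_e, 0, atol=1e-14)
    MA, MB, MAB, _ = brute_force_decomposition(
        X, fd.labels, ["i1", "i2"], ["j1", "j2"]
    )
    np.testing.assert_allclose(cd.M_A, MA, atol=1e-12)
    np.testing.assert_allclose(cd.M_AB, MAB, atol=1e-12)


def test_too_few_cells_for_residual_dof_errors():
    fd = make_design(2, 2, 1)
    em = make_expression(np.zeros((2, 4)))
    with pytest.raises(ValueError, match="residual dof"):
        compute_decomposition(em, fd)


# ------------------------------------------------------------------ contrast


def test_contrast_lambda_settings(rng):
    fd = make_design(2, 2, 3)
    em = make_expression(rng.normal(size=(4, 12)))
    cd = compute_decomposition(em, fd)
    np.testing.assert_allclose(
        build_contrast(cd, "feature_i", FLDAConfig(lambda1=0, lambda2=0)), cd.M_A
    )
    NA = build_contrast(cd, "feature_i", FLDAConfig(lambda1=1, lambda2=1))
    np.testing.assert_allclose(NA, cd.M_A - cd.M_B - cd.M_AB, atol=1e-12)
    assert np.max(np.abs(NA - NA.T)) < 1e-12
    NJ = build_contrast(cd, "feature_j", FLDAConfig())
    np.testing.assert_allclose(NJ, cd.M_B - cd.M_A - cd.M_AB, atol=1e-12)
    NI = build_contrast(cd, "interaction", FLDAConfig())
    np.testing.assert_allclose(NI, cd.M_AB - cd.M_A - cd.M_B, atol=1e-12)


# --------------------------------------------------------------- eigensolve


def test_single_informative_gene_gets_all_weight(rng):
    # only gene 1 varies (with feature i); all other genes are constant
    fd = make_design(2, 2, 5)
    X = np.zeros((4, 20))
    shift = np.array([2.0 if lab[0] == "i1" else -2.0 for lab in fd.labels])
    X[0] = shift + rng.normal(scale=0.05, size=20)
    basis = fit_flda(make_expression(X), fd, FLDAConfig(dims_per_component={"feature_i": 1}))
    axis = basis.component("feature_i")["axes"][0]
    assert np.argmax(np.abs(axis)) == 0
    assert np.abs(axis[0]) / np.abs(axis).sum() > 0.999


def test_2x4_design_yields_seven_axes(rng):
    fd = make_design(2, 4, 4)
    em = make_expression(rng.normal(size=(10, fd.n_cells)))
    basis = fit_flda(em, fd)
    assert sum(c["axes"].shape[0] for c in basis.components) == 7
    by_tag = {c["tag"]: c["axes"].shape[0] for c in basis.components}
    assert by_tag == {"feature_i": 1, "feature_j": 3, "interaction": 3}


def test_top_axis_beats_random_directions(rng):
    fd = make_design(2, 2, 6)
    em = make_expression(rng.normal(size=(10, fd.n_cells)))
    cfg = FLDAConfig(residual_mode="full")
    cd = compute_decomposition(em, fd)
    NA = build_contrast(cd, "feature_i", cfg)
    axes, vals = solve_component(NA, cd.M_e, 1)
    u = axes[0]
    top = (u @ NA @ u) / (u @ cd.M_e @ u)
    np.testing.assert_allclose(top, vals[0], rtol=1e-8)
    dirs = rng.normal(size=(1000, 10))
    quots = np.einsum("kg,gh,kh->k", dirs, NA, dirs) / np.einsum(
        "kg,gh,kh->k", dirs, cd.M_e, dirs
    )
    assert top >= quots.max() - 1e-10


def test_eigenvalues_non_increasing_and_Me_orthogonal(rng):
    fd = make_design(3, 3, 5)
    em = make_expression(rng.normal(size=(8, fd.n_cells)))
    cfg = FLDAConfig(residual_mode="full")
    res = FLDA(em, fd, residual_mode="full").fit()
    for comp in res.basis.components:
        vals = comp["eigenvalues"]
        assert np.all(np.diff(vals) <= 1e-10)
        A = comp["axes"]
        G = A @ res.decomposition.M_e @ A.T
        np.testing.assert_allclose(G, np.eye(len(vals)), atol=1e-8)


def test_zero_contrast_errors():
    with pytest.raises(ValueError, match="no signal"):
        solve_component(np.zeros((3, 3)), np.ones(3), 1)


def test_dims_exceeding_dof_errors(rng):
    fd = make_design(2, 2, 4)
    em = make_expression(rng.normal(size=(5, fd.n_cells)))
    with pytest.raises(ValueError, match="exceeds available dof"):
        FLDA(em, fd, dims={"feature_i": 2}).fit()


# ------------------------------------------------------------- fit behaviour


def test_fit_invariant_to_cell_permutation(rng):
    fd = make_design(2, 2, 5)
    em = make_expression(rng.normal(size=(6, fd.n_cells)))
    b1 = fit_flda(em, fd)
    perm = rng.permutation(fd.n_cells)
    em2 = ExpressionMatrix(
        em.values[:, perm], em.gene_ids, [em.cell_ids[p] for p in perm], "log"
    )
    fd2 = FactorDesign(
        [fd.cell_ids[p] for p in perm], fd.features, [fd.labels[p] for p in perm]
    )
    b2 = fit_flda(em2, fd2)
    np.testing.assert_allclose(b1.axes_matrix, b2.axes_matrix, atol=1e-10)


def test_fit_invariant_to_cell_duplication(rng):
    fd = make_design(2, 2, 4)
    em = make_expression(rng.normal(size=(5, fd.n_cells)))
    b1 = fit_flda(em, fd)
    em2 = ExpressionMatrix(
        np.hstack([em.values, em.values]),
        em.gene_ids,
        em.cell_ids + [f"dup_{c}" for c in em.cell_ids],
        "log",
    )
    fd2 = FactorDesign(em2.cell_ids, fd.features, fd.labels + fd.labels)
    b2 = fit_flda(em2, fd2)
    # duplicating cells rescales M_e's divisor; axes agree up to normalization
    for c1, c2 in zip(b1.components, b2.components):
        for u, v in zip(c1["axes"], c2["axes"]):
            cos = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            assert cos > 1 - 1e-8


def test_scale_equivariance(rng):
    fd = make_design(2, 2, 5)
    em = make_expression(rng.normal(size=(6, fd.n_cells)))
    b1 = fit_flda(em, fd)
    em2 = ExpressionMatrix(em.values * 7.5, em.gene_ids, em.cell_ids, "log")
    b2 = fit_flda(em2, fd)
    for c1, c2 in zip(b1.components, b2.components):
        np.testing.assert_allclose(c1["eigenvalues"], c2["eigenvalues"], rtol=1e-8)
        for u, v in zip(c1["axes"], c2["axes"]):
            cos = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
            assert cos > 1 - 1e-10


def test_single_feature_fit_matches_lda(rng):
    """Collapsing to one feature with both penalty weights 0 must give the
    Fisher discriminant direction of a two-class LDA."""
    from flda.baselines import lda_embed

    labels = [("i1", "j1")] * 6 + [("i2", "j1")] * 6
    fd = FactorDesign([f"c{k}" for k in range(12)], ["fi", "fj"], labels)
    X = rng.normal(size=(4, 12))
    X[1, 6:] += 3.0
    em = make_expression(X)
    basis = fit_flda(
        em, fd, FLDAConfig(lambda1=0, lambda2=0, residual_mode="full",
                           dims_per_component={"feature_i": 1})
    )
    u = basis.component("feature_i")["axes"][0]
    v = lda_embed(em, fd.feature_labels("fi"), r=1, residual_mode="full").axes[0]
    cos = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    assert cos > 1 - 1e-6


# ------------------------------------------------------------ partial tables


def partial_design():
    labels = [("i1", "j1")] * 4 + [("i1", "j2")] * 4 + [("i2", "j1")] * 4
    return FactorDesign([f"c{k}" for k in range(12)], ["fi", "fj"], labels)


def test_partial_table_refuses_interaction(rng):
    fd = partial_design()
    em = make_expression(rng.normal(size=(4, 12)))
    basis = fit_flda_partial(em, fd)
    assert {c["tag"] for c in basis.components} == {"feature_i", "feature_j"}
    with pytest.raises(ValueError, match="interaction"):
        fit_flda_partial(
            em, fd, FLDAConfig(dims_per_component={"interaction": 1})
        )
    with pytest.raises(ValueError, match="partial"):
        compute_decomposition(em, fd)


def test_partial_path_on_complete_table_equals_lambda2_zero(rng):
    fd = make_design(2, 2, 4)
    em = make_expression(rng.normal(size=(5, fd.n_cells)))
    b_partial = fit_flda_partial(em, fd, FLDAConfig(lambda1=1.0))
    b_full = fit_flda(em, fd, FLDAConfig(lambda1=1.0, lambda2=0.0))
    u = b_partial.component("feature_i")["axes"][0]
    v = b_full.component("feature_i")["axes"][0]
    cos = abs(u @ v) / (np.linalg.norm(u) * np.linalg.norm(v))
    assert cos > 1 - 1e-8


def test_additive_completion_recovers_partial_axis(rng):
    """If the missing cell type's data are consistent with additivity, the
    partial-table main-effect axis is close to the complete-table one."""
    g = 6
    mu = {}
    ri = rng.normal(size=g)
    rj = rng.normal(size=g)
    mu[("i1", "j1")] = np.zeros(g)
    mu[("i1", "j2")] = rj
    mu[("i2", "j1")] = ri
    mu[("i2", "j2")] = ri + rj  # additive completion: no interaction
    m = 40
    noise = 0.05
    labels_full, cols = [], []
    for t in mu:
        labels_full += [t] * m
        cols.append(mu[t][:, None] + rng.normal(scale=noise, size=(g, m)))
    X = np.hstack(cols)
    fd_full = FactorDesign([f"c{k}" for k in range(4 * m)], ["fi", "fj"], labels_full)
    em_full = make_expression(X)

    keep = [k for k, lab in enumerate(labels_full) if lab != ("i2", "j2")]
    fd_part = FactorDesign(
        [fd_full.cell_ids[k] for k in keep], ["fi", "fj"],
        [labels_full[k] for k in keep],
    )
    em_part = make_expression(X[:, keep])

    u_full = fit_flda(em_full, fd_full).component("feature_i")["axes"][0]
    u_part = fit_flda_partial(em_part, fd_part).component("feature_i")["axes"][0]
    cos = abs(u_full @ u_part) / (np.linalg.norm(u_full) * np.linalg.norm(u_part))
    assert cos > 0.98


# ---------------------------------------------------------------- projection


def test_projection_zero_vector_and_linearity(rng):
    fd = make_design(2, 2, 4)
    em = make_expression(rng.normal(size=(5, fd.n_cells)))
    res = FLDA(em, fd).fit()
    zero = ExpressionMatrix(np.zeros((5, 1)), em.gene_ids, ["z"], "log")
    np.testing.assert_allclose(project(zero, res.basis).coordinates, 0)

    cd = res.decomposition
    type_means = ExpressionMatrix(
        cd.cell_means.T, em.gene_ids, [str(t) for t in cd.types], "log"
    )
    lhs = project(type_means, res.basis).coordinates.mean(axis=1)
    grand = ExpressionMatrix(cd.grand_mean[:, None], em.gene_ids, ["gm"], "log")
    rhs = project(grand, res.basis).coordinates[:, 0]
    np.testing.assert_allclose(lhs, rhs, atol=1e-10)


def test_projection_gene_mismatch_errors(rng):
    fd = make_design(2, 2, 4)
    em = make_expression(rng.normal(size=(5, fd.n_cells)))
    res = FLDA(em, fd).fit()
    other = ExpressionMatrix(np.zeros((2, 1)), ["gX", "gY"], ["c"], "log")
    with pytest.raises(ValueError, match="lacks genes"):
        project(other, res.basis)


def test_projection_aligns_genes_by_id(rng):
    fd = make_design(2, 2, 4)
    em = make_expression(rng.normal(size=(5, fd.n_cells)))
    res = FLDA(em, fd).fit()
    perm = [3, 1, 4, 0, 2]
    em_perm = ExpressionMatrix(
        em.values[perm], [em.gene_ids[p] for p in perm], em.cell_ids, "log"
    )
    np.testing.assert_allclose(
        project(em_perm, res.basis).coordinates,
        res.project().coordinates,
        atol=1e-12,
    )
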