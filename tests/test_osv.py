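"""OSV domains, pair screening and the four-channel pseudo-energy tensor."""

import numpy as np
import pytest
from scipy.stats import spearmanr

from osvnet.geometry import Geometry
from osvnet.mp2 import PairKey, lmo_pair_energies
from osvnet.osv import (CHANNELS, DegeneracyError, OsvDomain,
                        build_osv_domain, channel_exchange_integrals,
                        channel_pseudo_amplitudes,
                        diagonal_semicanonical_amplitudes, featurize_context,
                        featurize_molecule, osv_cross_overlap,
                        pair_feature_tensor, pair_keep_decision)
from osvnet.synthetic import WATER_MONOMER, perturbed_conformers


def test_diagonal_amplitudes_symmetric_and_match_loop(water_631g):
    scf, lmos = water_631g
    ovov = scf.eri_ovov(lmos.c_lmo)
    for i in range(scf.n_occ):
        t = diagonal_semicanonical_amplitudes(scf, lmos, i)
        assert np.allclose(t, t.T, atol=1e-12)
        # element-by-element loop oracle
        f_ii = lmos.fock_lmo[i, i]
        for a in range(scf.n_virt):
            for b in range(scf.n_virt):
                ref = -ovov[i, a, i, b] / (scf.eps_virt[a] + scf.eps_virt[b]
                                           - 2.0 * f_ii)
                assert t[a, b] == pytest.approx(ref, abs=1e-14)


def test_osv_domain_orthonormal_descending_and_reconstructs(water_631g):
    scf, lmos = water_631g
    t = diagonal_semicanonical_amplitudes(scf, lmos, 0)
    # full-rank domain reconstructs t_ii
    dom = build_osv_domain(t, scf.n_virt, scf, lmos, 0)
    assert np.allclose(dom.q.T @ dom.q, np.eye(scf.n_virt), atol=1e-10)
    assert np.all(np.diff(dom.singular_values) <= 1e-12)
    u, s, vt = np.linalg.svd(t)
    recon = u @ np.diag(s) @ vt
    assert np.allclose(recon, t, atol=1e-10)
    # truncated singular values match the dense-SVD oracle
    dom4 = build_osv_domain(t, 4, scf, lmos, 0)
    assert np.allclose(dom4.singular_values, np.sort(s)[::-1][:4], atol=1e-10)
    # OSV Fock diagonal equals the rotated virtual Fock diagonal
    f_virt = np.diag(scf.eps_virt)
    assert np.allclose(dom4.fock_osv_diag,
                       np.diag(dom4.q.T @ f_virt @ dom4.q), atol=1e-12)


def test_rank_one_amplitudes_give_single_osv():
    v = np.array([1.0, 2.0, -1.0, 0.5])
    t = np.outer(v, v)
    scf = type("S", (), {"eps_virt": np.ones(4)})()
    dom = build_osv_domain(t, 4, scf, None, 0)
    assert dom.singular_values[0] > 1e-10
    assert np.all(dom.singular_values[1:] < 1e-12)
    assert abs(abs(np.dot(dom.q[:, 0], v / np.linalg.norm(v))) - 1) < 1e-12


def test_osv_count_cannot_exceed_virtual_space(water_sto3g):
    scf, lmos = water_sto3g
    t = diagonal_semicanonical_amplitudes(scf, lmos, 0)
    with pytest.raises(ValueError):
        build_osv_domain(t, scf.n_virt + 1, scf, lmos, 0)


# ---------------------------------------------------------------- screening

def test_diagonal_pairs_always_kept_and_orthogonal_spaces_discarded():
    q1 = np.eye(4)[:, :2]
    q2 = np.eye(4)[:, 2:]
    d1 = OsvDomain(0, q1, np.ones(2), np.ones(2))
    d2 = OsvDomain(1, q2, np.ones(2), np.ones(2))
    d1b = OsvDomain(0, q1, np.ones(2), np.ones(2))
    assert pair_keep_decision(d1, d1b, None, cutoff=10.0)   # same LMO index
    assert not pair_keep_decision(d1, d2, None, cutoff=1e-300)


def test_far_separated_fragments_screened_matching_bruteforce():
    far = Geometry(
        WATER_MONOMER.atoms * 2,
        np.vstack([WATER_MONOMER.coords,
                   WATER_MONOMER.coords + np.array([50.0, 0, 0])]))
    fs, scf, lmos = featurize_molecule(far, "sto-3g", n_osv=2,
                                       cutoff=3.2e-5)
    # fragment of each LMO by the atom holding its largest population
    from osvnet.scf import _mulliken_charges
    Q = _mulliken_charges(lmos.c_lmo, scf.overlap_ao, scf.ao_atom_indices,
                          scf.geometry.n_atoms)
    frag = (Q.argmax(axis=0) >= 3).astype(int)
    inter = [k for k in fs.keys if frag[k.i] != frag[k.j]]
    assert inter == []  # all inter-fragment pairs screened out
    # brute-force all-pairs screening agrees with the kept set
    ovov = scf.eri_ovov(lmos.c_lmo)
    doms = [build_osv_domain(
        diagonal_semicanonical_amplitudes(scf, lmos, i, ovov), 2, scf,
        lmos, i) for i in range(scf.n_occ)]
    kept_brute = set()
    for i in range(scf.n_occ):
        for j in range(i, scf.n_occ):
            smax = np.linalg.svd(osv_cross_overlap(doms[i], doms[j]),
                                 compute_uv=False)[0]
            if i == j or smax >= 3.2e-5:
                kept_brute.add(PairKey(i, j))
    assert set(fs.keys) == kept_brute


def test_screening_monotone_in_cutoff(dimer_sto3g):
    scf, lmos = dimer_sto3g
    loose = featurize_context(scf, lmos, n_osv=2, cutoff=1e-8)
    tight = featurize_context(scf, lmos, n_osv=2, cutoff=1e-1)
    assert set(tight.keys) <= set(loose.keys)


# ----------------------------------------------------------------- channels

def test_identity_rotation_recovers_raw_integral_blocks(water_631g):
    scf, lmos = water_631g
    ovov = scf.eri_ovov(lmos.c_lmo)
    q = np.eye(scf.n_virt)
    f = np.diag(np.diag(np.eye(scf.n_virt)))
    di = OsvDomain(0, q, np.ones(scf.n_virt), scf.eps_virt)
    dj = OsvDomain(1, q, np.ones(scf.n_virt), scf.eps_virt)
    k = channel_exchange_integrals(scf, lmos, di, dj)
    assert np.allclose(k["vt"], ovov[0, :, 1, :], atol=1e-12)
    assert np.allclose(k["ex"], ovov[0, :, 1, :], atol=1e-12)


def test_channels_match_dense_contraction_oracle(dimer_sto3g):
    scf, lmos = dimer_sto3g
    ovov = scf.eri_ovov(lmos.c_lmo)
    i, j = 0, 1
    doms = {}
    for idx in (i, j):
        t = diagonal_semicanonical_amplitudes(scf, lmos, idx)
        doms[idx] = build_osv_domain(t, 2, scf, lmos, idx)
    k = channel_exchange_integrals(scf, lmos, doms[i], doms[j])
    k_ab = ovov[i, :, j, :]
    qi, qj = doms[i].q, doms[j].q
    assert np.allclose(k["vt"], np.einsum("am,ab,bn->mn", qi, k_ab, qj),
                       atol=1e-12)
    assert np.allclose(k["ex"], np.einsum("am,ab,bn->mn", qj, k_ab, qi),
                       atol=1e-12)
    assert np.allclose(k["ct1"], np.einsum("am,ab,bn->mn", qi, k_ab, qi),
                       atol=1e-12)
    assert np.allclose(k["ct2"], np.einsum("am,ab,bn->mn", qj, k_ab, qj),
                       atol=1e-12)


def test_diagonal_pair_channels_coincide_and_vt_symmetric(water_631g):
    scf, lmos = water_631g
    t = diagonal_semicanonical_amplitudes(scf, lmos, 0)
    dom = build_osv_domain(t, 4, scf, lmos, 0)
    k = channel_exchange_integrals(scf, lmos, dom, dom)
    for ch in CHANNELS[1:]:
        assert np.allclose(k["vt"], k[ch], atol=1e-12)
    assert np.allclose(k["vt"], k["vt"].T, atol=1e-12)


def test_pseudo_amplitudes_semicanonical_limit():
    """With Fock exactly diagonal in the OSV basis the pseudo-amplitudes
    equal the directly solved semicanonical amplitudes."""
    rng = np.random.default_rng(5)
    n = 3
    k = rng.normal(size=(n, n)) * 0.01
    f_osv = np.array([0.4, 0.7, 1.1])
    f_ii = f_jj = -0.45
    di = OsvDomain(0, np.eye(n), np.ones(n), f_osv)
    dj = OsvDomain(1, np.eye(n), np.ones(n), f_osv)
    t = channel_pseudo_amplitudes({"vt": k}, f_ii, f_jj, di, dj)["vt"]
    for a in range(n):
        for bq in range(n):
            exact = -k[a, bq] / (f_osv[a] + f_osv[bq] - f_ii - f_jj)
            assert t[a, bq] == pytest.approx(exact, abs=1e-15)
    # zero integrals give zero amplitudes
    t0 = channel_pseudo_amplitudes({"vt": np.zeros((n, n))}, f_ii, f_jj,
                                   di, dj)["vt"]
    assert np.all(t0 == 0.0)


def test_near_degenerate_denominator_raises():
    di = OsvDomain(0, np.eye(2), np.ones(2), np.array([0.5, 0.5]))
    dj = OsvDomain(1, np.eye(2), np.ones(2), np.array([0.5, 0.5]))
    with pytest.raises(DegeneracyError):
        channel_pseudo_amplitudes({"vt": np.ones((2, 2))}, 0.5, 0.5, di, dj)


# ----------------------------------------------------------- feature tensor

def test_symmetric_amplitudes_reduce_contravariant_to_plain_product():
    rng = np.random.default_rng(2)
    k = {ch: rng.normal(size=(3, 3)) for ch in CHANNELS}
    t_sym = rng.normal(size=(3, 3))
    t_sym = t_sym + t_sym.T
    t = {"vt": t_sym, "ex": t_sym.T, "ct1": t_sym, "ct2": t_sym}
    feat = pair_feature_tensor(k, t, PairKey(0, 1))
    assert np.allclose(feat.tensor[0], k["vt"] * t_sym, atol=1e-14)


def test_feature_tensor_gauge_invariant_under_osv_sign_flips(water_631g):
    scf, lmos = water_631g
    ovov = scf.eri_ovov(lmos.c_lmo)
    i, j = 0, 2
    doms = {}
    for idx in (i, j):
        t = diagonal_semicanonical_amplitudes(scf, lmos, idx)
        doms[idx] = build_osv_domain(t, 4, scf, lmos, idx)

    def tensor_for(di, dj):
        k = channel_exchange_integrals(scf, lmos, di, dj)
        t = channel_pseudo_amplitudes(k, lmos.fock_lmo[i, i],
                                      lmos.fock_lmo[j, j], di, dj)
        return pair_feature_tensor(k, t, PairKey(i, j)).tensor

    ref = tensor_for(doms[i], doms[j])
    rng = np.random.default_rng(0)
    for _ in range(3):
        flips_i = rng.choice([-1.0, 1.0], size=4)
        flips_j = rng.choice([-1.0, 1.0], size=4)
        di = OsvDomain(i, doms[i].q * flips_i, doms[i].singular_values,
                       doms[i].fock_osv_diag)
        dj = OsvDomain(j, doms[j].q * flips_j, doms[j].singular_values,
                       doms[j].fock_osv_diag)
        assert np.allclose(tensor_for(di, dj), ref, atol=1e-12)


def test_diagonal_feature_matches_bruteforce_element_loop(water_631g):
    scf, lmos = water_631g
    ovov = scf.eri_ovov(lmos.c_lmo)
    i = 1
    t_ii = diagonal_semicanonical_amplitudes(scf, lmos, i)
    dom = build_osv_domain(t_ii, 4, scf, lmos, i)
    k = channel_exchange_integrals(scf, lmos, dom, dom)
    t = channel_pseudo_amplitudes(k, lmos.fock_lmo[i, i],
                                  lmos.fock_lmo[i, i], dom, dom)
    feat = pair_feature_tensor(k, t, PairKey(i, i)).tensor
    f_ii = lmos.fock_lmo[i, i]
    q = dom.q
    for m in range(4):
        for n in range(4):
            k_mn = q[:, m] @ ovov[i, :, i, :] @ q[:, n]
            den = dom.fock_osv_diag[m] + dom.fock_osv_diag[n] - 2 * f_ii
            t_mn = -k_mn / den
            k_nm = q[:, n] @ ovov[i, :, i, :] @ q[:, m]
            t_nm = -k_nm / (dom.fock_osv_diag[n] + dom.fock_osv_diag[m]
                            - 2 * f_ii)
            assert feat[0, m, n] == pytest.approx(k_mn * (2 * t_mn - t_nm),
                                                  abs=1e-13)


# ------------------------------------------------------------ full pipeline

def test_featurize_molecule_counts_and_determinism(water_sto3g):
    fs1, _, _ = featurize_molecule(WATER_MONOMER, "sto-3g", n_osv=2)
    fs2, _, _ = featurize_molecule(WATER_MONOMER, "sto-3g", n_osv=2)
    n = fs1.n_occ
    assert len(fs1.features) + len(fs1.screened_out) == n * (n + 1) // 2
    assert len(fs1.screened_out) == 0
    for f1, f2 in zip(fs1.features, fs2.features):
        assert f1.key == f2.key
        assert np.array_equal(f1.tensor, f2.tensor)  # bitwise


def test_diagonal_vt_sums_track_exact_pair_energies():
    """Across perturbed conformers, the vt-channel sum of diagonal pairs is
    negative and rank-correlates strongly with the exact pair energies."""
    confs = perturbed_conformers(WATER_MONOMER, 8, 0.02, seed=11)
    sums, exact = [], []
    for g in confs:
        fs, scf, lmos = featurize_molecule(g, "sto-3g", n_osv=2)
        tab = lmo_pair_energies(scf, lmos)
        for f in fs.diagonal():
            sums.append(float(f.tensor[0].sum()))
            exact.append(tab[f.key])
    assert all(s < 0 for s in sums)
    rho = spearmanr(sums, exact).statistic
    assert rho >= 0.8
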