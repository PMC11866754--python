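"""Gaussian integrals over contracted s/p shells (McMurchie–Davidson).

Computes AO overlap, kinetic, nuclear-attraction matrices and the full
two-electron repulsion tensor in chemist's notation (μν|λσ).  Kernels are
numba-compiled; sizes are small (≤ ~30 atoms in a double-zeta basis) so the
full ERI tensor is held in memory.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .basis import ANGULAR_COMPONENTS, BasisSet

_SQRT_PI = np.sqrt(np.pi)


# ---------------------------------------------------------------- Boys F_m(t)

@njit(cache=True)
def _boys(m_max, t, out):
    """Fill out[0..m_max] with Boys functions F_m(t)."""
    if t < 1e-13:
        for m in range(m_max + 1):
            out[m] = 1.0 / (2.0 * m + 1.0)
        return
    if t < 35.0:
        # series for F_mmax, then downward recursion
        emt = np.exp(-t)
        num = 1.0
        den = 2.0 * m_max + 1.0
        term = num / den
        total = term
        k = 1
        while term > 1e-17 * total and k < 300:
            term *= 2.0 * t / (2.0 * m_max + 2.0 * k + 1.0)
            total += term
            k += 1
        out[m_max] = total * emt
        for m in range(m_max - 1, -1, -1):
            out[m] = (2.0 * t * out[m + 1] + emt) / (2.0 * m + 1.0)
    else:
        # erf(sqrt(t)) == 1 to machine precision for t >= 35
        emt = np.exp(-t) if t < 700.0 else 0.0
        out[0] = 0.5 * np.sqrt(np.pi / t)
        for m in range(m_max):
            out[m + 1] = ((2.0 * m + 1.0) * out[m] - emt) / (2.0 * t)


# ------------------------------------------- Hermite expansion E_t^{ij} table

@njit(cache=True)
def _e_table(l1, l2, pa, pb, p, kab, E):
    """Fill E[i, j, t] for i<=l1, j<=l2, t<=i+j; E pre-zeroed caller-side."""
    oo2p = 0.5 / p
    E[0, 0, 0] = kab
    for i in range(l1 + 1):
        for j in range(l2 + 1):
            if i == 0 and j == 0:
                continue
            if j == 0:
                # build from (i-1, 0)
                for t in range(i + 1):
                    v = pa * E[i - 1, 0, t]
                    if t > 0:
                        v += oo2p * E[i - 1, 0, t - 1]
                    if t + 1 <= i - 1:
                        v += (t + 1) * E[i - 1, 0, t + 1]
                    E[i, 0, t] = v
            else:
                for t in range(i + j + 1):
                    v = pb * E[i, j - 1, t]
                    if t > 0:
                        v += oo2p * E[i, j - 1, t - 1]
                    if t + 1 <= i + j - 1:
                        v += (t + 1) * E[i, j - 1, t + 1]
                    E[i, j, t] = v


# ------------------------------------------------- Hermite Coulomb R_{tuv}

@njit(cache=True)
def _r_table(tmax, umax, vmax, p, px, py, pz, R):
    """Fill R[t,u,v] = R^0_{tuv}(p, P) via auxiliary order recursion."""
    nmax = tmax + umax + vmax
    t2 = px * px + py * py + pz * pz
    F = np.zeros(nmax + 1)
    _boys(nmax, p * t2, F)
    # Rn[n, t, u, v]
    Rn = np.zeros((nmax + 1, tmax + 1, umax + 1, vmax + 1))
    for n in range(nmax + 1):
        Rn[n, 0, 0, 0] = (-2.0 * p) ** n * F[n]
    for total in range(1, nmax + 1):
        for t in range(min(total, tmax) + 1):
            for u in range(min(total - t, umax) + 1):
                v = total - t - u
                if v < 0 or v > vmax:
                    continue
                for n in range(nmax - total + 1):
                    if v > 0:
                        val = pz * Rn[n + 1, t, u, v - 1]
                        if v > 1:
                            val += (v - 1) * Rn[n + 1, t, u, v - 2]
                    elif u > 0:
                        val = py * Rn[n + 1, t, u - 1, v]
                        if u > 1:
                            val += (u - 1) * Rn[n + 1, t, u - 2, v]
                    else:
                        val = px * Rn[n + 1, t - 1, u, v]
                        if t > 1:
                            val += (t - 1) * Rn[n + 1, t - 2, u, v]
                    Rn[n, t, u, v] = val
    for t in range(tmax + 1):
        for u in range(umax + 1):
            for v in range(vmax + 1):
                R[t, u, v] = Rn[0, t, u, v]


@njit(cache=True)
def _comp_lmn(l, comp):
    if l == 0:
        return 0, 0, 0
    if comp == 0:
        return 1, 0, 0
    if comp == 1:
        return 0, 1, 0
    return 0, 0, 1


@njit(cache=True)
def _one_electron(shell_l, centers, prim_start, prim_count, ao_start,
                  exps, coefs, atom_z, atom_pos, S, T, V):
    ns = shell_l.shape[0]
    natm = atom_z.shape[0]
    for sa in range(ns):
        la = shell_l[sa]
        A = centers[sa]
        for sb in range(sa + 1):
            lb = shell_l[sb]
            B = centers[sb]
            nfa = 1 if la == 0 else 3
            nfb = 1 if lb == 0 else 3
            sblk = np.zeros((nfa, nfb))
            tblk = np.zeros((nfa, nfb))
            vblk = np.zeros((nfa, nfb))
            ab2 = 0.0
            for d in range(3):
                ab2 += (A[d] - B[d]) ** 2
            for ia in range(prim_start[sa], prim_start[sa] + prim_count[sa]):
                a = exps[ia]
                ca = coefs[ia]
                for ib in range(prim_start[sb],
                                prim_start[sb] + prim_count[sb]):
                    b = exps[ib]
                    cb = coefs[ib]
                    p = a + b
                    mu = a * b / p
                    Px = (a * A[0] + b * B[0]) / p
                    Py = (a * A[1] + b * B[1]) / p
                    Pz = (a * A[2] + b * B[2]) / p
                    # E tables per dimension, with lb extended by 2 for
                    # kinetic; each dimension carries its own Gaussian
                    # product prefactor exp(-mu dx^2)
                    Ex = np.zeros((la + 1, lb + 3, la + lb + 3))
                    Ey = np.zeros((la + 1, lb + 3, la + lb + 3))
                    Ez = np.zeros((la + 1, lb + 3, la + lb + 3))
                    _e_table(la, lb + 2, Px - A[0], Px - B[0], p,
                             np.exp(-mu * (A[0] - B[0]) ** 2), Ex)
                    _e_table(la, lb + 2, Py - A[1], Py - B[1], p,
                             np.exp(-mu * (A[1] - B[1]) ** 2), Ey)
                    _e_table(la, lb + 2, Pz - A[2], Pz - B[2], p,
                             np.exp(-mu * (A[2] - B[2]) ** 2), Ez)
                    spi = _SQRT_PI / np.sqrt(p)
                    cc = ca * cb
                    for fa in range(nfa):
                        l1, m1, n1 = _comp_lmn(la, fa)
                        for fb in range(nfb):
                            l2, m2, n2 = _comp_lmn(lb, fb)
                            sx = Ex[l1, l2, 0] * spi
                            sy = Ey[m1, m2, 0] * spi
                            sz = Ez[n1, n2, 0] * spi
                            sblk[fa, fb] += cc * sx * sy * sz
                            # 1D kinetic parts
                            tx = b * (2 * l2 + 1) * Ex[l1, l2, 0] \
                                - 2.0 * b * b * Ex[l1, l2 + 2, 0]
                            if l2 >= 2:
                                tx -= 0.5 * l2 * (l2 - 1) * Ex[l1, l2 - 2, 0]
                            tx *= spi
                            ty = b * (2 * m2 + 1) * Ey[m1, m2, 0] \
                                - 2.0 * b * b * Ey[m1, m2 + 2, 0]
                            if m2 >= 2:
                                ty -= 0.5 * m2 * (m2 - 1) * Ey[m1, m2 - 2, 0]
                            ty *= spi
                            tz = b * (2 * n2 + 1) * Ez[n1, n2, 0] \
                                - 2.0 * b * b * Ez[n1, n2 + 2, 0]
                            if n2 >= 2:
                                tz -= 0.5 * n2 * (n2 - 1) * Ez[n1, n2 - 2, 0]
                            tz *= spi
                            tblk[fa, fb] += cc * (tx * sy * sz + sx * ty * sz
                                                  + sx * sy * tz)
                            # nuclear attraction
                            tmax = l1 + l2
                            umax = m1 + m2
                            vmax = n1 + n2
                            vsum = 0.0
                            for ic in range(natm):
                                R = np.zeros((tmax + 1, umax + 1, vmax + 1))
                                _r_table(tmax, umax, vmax, p,
                                         Px - atom_pos[ic, 0],
                                         Py - atom_pos[ic, 1],
                                         Pz - atom_pos[ic, 2], R)
                                acc = 0.0
                                for t in range(tmax + 1):
                                    for u in range(umax + 1):
                                        for v in range(vmax + 1):
                                            acc += Ex[l1, l2, t] \
                                                * Ey[m1, m2, u] \
                                                * Ez[n1, n2, v] * R[t, u, v]
                                vsum -= atom_z[ic] * acc
                            vblk[fa, fb] += cc * vsum * 2.0 * np.pi / p
            oa = ao_start[sa]
            ob = ao_start[sb]
            for fa in range(nfa):
                for fb in range(nfb):
                    S[oa + fa, ob + fb] = sblk[fa, fb]
                    S[ob + fb, oa + fa] = sblk[fa, fb]
                    T[oa + fa, ob + fb] = tblk[fa, fb]
                    T[ob + fb, oa + fa] = tblk[fa, fb]
                    V[oa + fa, ob + fb] = vblk[fa, fb]
                    V[ob + fb, oa + fa] = vblk[fa, fb]


@njit(cache=True)
def _hermite_density(la, lb, A, B, a, b, cc):
    """Per-dimension E tables and geometric prefactors for a shell pair."""
    p = a + b
    mu = a * b / p
    P = np.empty(3)
    for d in range(3):
        P[d] = (a * A[d] + b * B[d]) / p
    Ex = np.zeros((la + 1, lb + 1, la + lb + 1))
    Ey = np.zeros((la + 1, lb + 1, la + lb + 1))
    Ez = np.zeros((la + 1, lb + 1, la + lb + 1))
    _e_table(la, lb, P[0] - A[0], P[0] - B[0], p,
             np.exp(-mu * (A[0] - B[0]) ** 2), Ex)
    _e_table(la, lb, P[1] - A[1], P[1] - B[1], p,
             np.exp(-mu * (A[1] - B[1]) ** 2), Ey)
    _e_table(la, lb, P[2] - A[2], P[2] - B[2], p,
             np.exp(-mu * (A[2] - B[2]) ** 2), Ez)
    return p, P, Ex, Ey, Ez


@njit(cache=True)
def _eri_tensor(shell_l, centers, prim_start, prim_count, ao_start,
                exps, coefs, eri):
    """Full (μν|λσ) tensor using shell-quartet loops + 8-fold symmetry."""
    ns = shell_l.shape[0]
    for sa in range(ns):
        la = shell_l[sa]
        A = centers[sa]
        nfa = 1 if la == 0 else 3
        for sb in range(sa + 1):
            lb = shell_l[sb]
            B = centers[sb]
            nfb = 1 if lb == 0 else 3
            for sc in range(sa + 1):
                lc = shell_l[sc]
                C = centers[sc]
                nfc = 1 if lc == 0 else 3
                sd_max = sb if sc == sa else sc
                for sd in range(sd_max + 1):
                    ld = shell_l[sd]
                    D = centers[sd]
                    nfd = 1 if ld == 0 else 3
                    blk = np.zeros((nfa, nfb, nfc, nfd))
                    for ia in range(prim_start[sa],
                                    prim_start[sa] + prim_count[sa]):
                        a = exps[ia]
                        for ib in range(prim_start[sb],
                                        prim_start[sb] + prim_count[sb]):
                            b = exps[ib]
                            p, P, Exab, Eyab, Ezab = _hermite_density(
                                la, lb, A, B, a, b, 1.0)
                            cab = coefs[ia] * coefs[ib]
                            for ic in range(prim_start[sc],
                                            prim_start[sc] + prim_count[sc]):
                                c = exps[ic]
                                for idd in range(
                                        prim_start[sd],
                                        prim_start[sd] + prim_count[sd]):
                                    d = exps[idd]
                                    q, Q, Excd, Eycd, Ezcd = _hermite_density(
                                        lc, ld, C, D, c, d, 1.0)
                                    ccd = coefs[ic] * coefs[idd]
                                    alpha = p * q / (p + q)
                                    pref = 2.0 * np.pi ** 2.5 / (
                                        p * q * np.sqrt(p + q)) * cab * ccd
                                    tmx = la + lb + lc + ld
                                    R = np.zeros((tmx + 1, tmx + 1, tmx + 1))
                                    _r_table(tmx, tmx, tmx, alpha,
                                             P[0] - Q[0], P[1] - Q[1],
                                             P[2] - Q[2], R)
                                    for fa in range(nfa):
                                        l1, m1, n1 = _comp_lmn(la, fa)
                                        for fb in range(nfb):
                                            l2, m2, n2 = _comp_lmn(lb, fb)
                                            for fc in range(nfc):
                                                l3, m3, n3 = _comp_lmn(lc, fc)
                                                for fd in range(nfd):
                                                    l4, m4, n4 = _comp_lmn(
                                                        ld, fd)
                                                    acc = 0.0
                                                    for t in range(l1 + l2 + 1):
                                                        for u in range(
                                                                m1 + m2 + 1):
                                                            for v in range(
                                                                    n1 + n2
                                                                    + 1):
                                                                e1 = Exab[l1, l2, t] * Eyab[m1, m2, u] * Ezab[n1, n2, v]
                                                                if e1 == 0.0:
                                                                    continue
                                                                for tt in range(l3 + l4 + 1):
                                                                    for uu in range(m3 + m4 + 1):
                                                                        for vv in range(n3 + n4 + 1):
                                                                            e2 = Excd[l3, l4, tt] * Eycd[m3, m4, uu] * Ezcd[n3, n4, vv]
                                                                            if e2 == 0.0:
                                                                                continue
                                                                            sgn = 1.0 if (tt + uu + vv) % 2 == 0 else -1.0
                                                                            acc += e1 * e2 * sgn * R[t + tt, u + uu, v + vv]
                                                    blk[fa, fb, fc, fd] += \
                                                        pref * acc
                    # scatter with 8-fold symmetry
                    oa = ao_start[sa]
                    ob = ao_start[sb]
                    oc = ao_start[sc]
                    od = ao_start[sd]
                    for fa in range(nfa):
                        for fb in range(nfb):
                            for fc in range(nfc):
                                for fd in range(nfd):
                                    val = blk[fa, fb, fc, fd]
                                    i = oa + fa
                                    j = ob + fb
                                    k = oc + fc
                                    ll = od + fd
                                    eri[i, j, k, ll] = val
                                    eri[j, i, k, ll] = val
                                    eri[i, j, ll, k] = val
                                    eri[j, i, ll, k] = val
                                    eri[k, ll, i, j] = val
                                    eri[ll, k, i, j] = val
                                    eri[k, ll, j, i] = val
                                    eri[ll, k, j, i] = val


def _flatten(basis: BasisSet):
    shells = basis.shells
    shell_l = np.array([sh.l for sh in shells], dtype=np.int64)
    centers = np.array([sh.center for sh in shells], dtype=float)
    prim_count = np.array([len(sh.exponents) for sh in shells], dtype=np.int64)
    prim_start = np.concatenate([[0], np.cumsum(prim_count)[:-1]]).astype(
        np.int64)
    exps = np.concatenate([sh.exponents for sh in shells])
    coefs = np.concatenate([sh.coefficients for sh in shells])
    ao_start = basis.ao_offsets[:-1].astype(np.int64)
    return shell_l, centers, prim_start, prim_count, ao_start, exps, coefs


def one_electron_integrals(basis: BasisSet):
    """Return (S, T, V) AO matrices in Hartree atomic units."""
    n = basis.n_ao
    S = np.zeros((n, n))
    T = np.zeros((n, n))
    V = np.zeros((n, n))
    geom = basis.geometry
    _one_electron(*_flatten(basis), geom.atomic_numbers.astype(float),
                  geom.coords_bohr(), S, T, V)
    return S, T, V


def eri_tensor(basis: BasisSet) -> np.ndarray:
    """Full AO two-electron tensor (μν|λσ), chemist's notation."""
    n = basis.n_ao
    eri = np.zeros((n, n, n, n))
    _eri_tensor(*_flatten(basis), eri)
    return eri


def boys_function(m: int, t: float) -> float:
    """Boys function F_m(t) (exposed for testing)."""
    out = np.zeros(m + 1)
    _boys(m, float(t), out)
    return float(out[m])
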