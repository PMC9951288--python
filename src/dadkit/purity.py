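"""Peak purity assessment and library-constrained PARAFAC deconvolution.

A detected peak window is *pure* when every spectrum across the window
matches the apex spectrum (Pearson correlation) and the window's
absorbance slab is effectively rank one (first-principal-component
explained variance).  Impure windows are deconvolved: PCA on the slab
estimates the number of coeluting components, the slab is stacked with
retention-aligned reference slabs of candidate library compounds into a
trilinear time x wavelength x slab tensor, and a non-negative PARAFAC
model is fitted by multi-restart alternating least squares.  Each
recovered component carries an elution profile, a spectrum, per-slab
loadings and an integral; integrals are anchored so their sum equals the
impure window's summed-trace integral, keeping deconvolved areas
commensurate with ordinary peak integration and calibration curves.

PARAFAC (canonical polyadic decomposition) is unique under mild
conditions even for heavily collinear elution profiles, which is what
makes spectral deconvolution of coeluting chromatographic peaks
possible where single-wavelength analysis cannot succeed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy.linalg import svd

from .io import Chromatogram
from .peaks import Peak

__all__ = [
    "Spectrum", "PurityReport", "DeconvComponent", "ParafacResult",
    "DeconvolutionError", "spectrum_at", "pearson_similarity", "check_purity",
    "estimate_component_count", "build_tensor", "parafac_nnls", "deconvolve",
]

MIN_PURITY_WINDOW = 5
#: windows wider than this are subsampled 2x for PCA only (never integration)
PCA_SUBSAMPLE_WIDTH = 120


class DeconvolutionError(RuntimeError):
    """PARAFAC failed on all restarts; the window stays unresolved."""


@dataclass
class Spectrum:
    """A unit-norm UV-Vis absorbance spectrum on the campaign grid."""

    wavelength: np.ndarray
    values: np.ndarray
    source: str = "apex"  # apex extraction | library | deconvolved | simulated

    def __post_init__(self):
        self.wavelength = np.asarray(self.wavelength, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if v.shape != self.wavelength.shape:
            raise ValueError("spectrum and grid lengths differ")
        if np.any(v < -1e-6):
            raise ValueError("spectrum has significantly negative values")
        v = np.clip(v, 0.0, None)
        norm = np.linalg.norm(v)
        if norm == 0:
            raise ValueError("all-zero spectrum")
        self.values = v / norm


def spectrum_at(chrom: Chromatogram, t_index: int) -> Spectrum:
    """Unit-normalized spectrum at one time point."""
    row = chrom.absorbance[t_index]
    if np.linalg.norm(np.clip(row, 0.0, None)) == 0:
        raise ValueError(f"no spectrum at index {t_index}: all-zero row")
    return Spectrum(chrom.wavelength, np.clip(row, 0.0, None), source="apex")


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ac = a - a.mean()
    bc = b - b.mean()
    na = np.linalg.norm(ac)
    nb = np.linalg.norm(bc)
    if na == 0 or nb == 0:
        raise ValueError("zero-variance vector in correlation")
    return float(np.clip(ac @ bc / (na * nb), -1.0, 1.0))


def pearson_similarity(s1: Spectrum, s2: Spectrum) -> float:
    """Pearson correlation of two spectra on the same wavelength grid."""
    if s1.wavelength.shape != s2.wavelength.shape or not np.allclose(
        s1.wavelength, s2.wavelength
    ):
        raise ValueError("spectra are on different wavelength grids")
    return _pearson(s1.values, s2.values)


@dataclass(frozen=True)
class PurityReport:
    """Outcome of the two-test purity check on one peak window."""

    pure: bool
    min_correlation: float
    pca_explained_1: float
    n_sampled: int

    def __post_init__(self):
        if not -1.0 <= self.min_correlation <= 1.0:
            raise ValueError("min_correlation outside [-1, 1]")
        if not 0.0 <= self.pca_explained_1 <= 1.0 + 1e-12:
            raise ValueError("explained variance outside [0, 1]")


def _pca_slab(slab: np.ndarray) -> np.ndarray:
    """Slab used for PCA: 2x time-subsampled when very wide."""
    if slab.shape[0] > PCA_SUBSAMPLE_WIDTH:
        return slab[::2]
    return slab


def check_purity(chrom: Chromatogram, peak: Peak,
                 r_min: float = 0.95, ev_min: float = 0.995) -> PurityReport:
    """Two-test purity verdict for a peak window.

    Test 1: the minimum Pearson correlation between the apex spectrum and
    the spectrum at every in-window point whose summed absorbance reaches
    10% of the apex height must be >= ``r_min``.  Test 2: the first
    principal component of the time-mean-centered window slab must
    explain >= ``ev_min`` of the variance.  Both must pass for a pure
    verdict; a strongly coeluting pair with near-identical spectra will
    pass both (the documented false-positive mode, unresolvable from the
    data alone).
    """
    if peak.width < MIN_PURITY_WINDOW:
        raise ValueError(f"window of {peak.width} points too narrow for purity check")
    sl = slice(peak.left_index, peak.right_index + 1)
    slab = chrom.absorbance[sl]
    trace = slab.sum(axis=1)
    apex_local = peak.apex_index - peak.left_index
    apex_spec = spectrum_at(chrom, peak.apex_index)
    height_floor = 0.10 * trace[apex_local]
    sampled = np.flatnonzero(trace >= height_floor)
    rs = []
    for i in sampled:
        try:
            rs.append(pearson_similarity(
                spectrum_at(chrom, peak.left_index + int(i)), apex_spec))
        except ValueError:
            rs.append(0.0)
    min_r = float(min(rs)) if rs else 0.0

    centered = _pca_slab(slab)
    centered = centered - centered.mean(axis=0, keepdims=True)
    s = svd(centered, compute_uv=False)
    total = float(np.sum(s**2))
    ev1 = float(s[0] ** 2 / total) if total > 0 else 1.0

    pure = (min_r >= r_min) and (ev1 >= ev_min)
    return PurityReport(pure=pure, min_correlation=min_r,
                        pca_explained_1=ev1, n_sampled=int(sampled.size))


def estimate_component_count(slab: np.ndarray, ev_total: float = 0.995,
                             k_max: int = 4) -> int:
    """Number of coeluting components from the slab's singular spectrum.

    The smallest k whose leading principal components of the
    time-mean-centered slab explain >= ``ev_total`` of the variance,
    capped at ``k_max``.  Centering matches the purity check's variance
    decomposition, so a window flagged impure always yields k >= 2.
    """
    slab = np.asarray(slab, dtype=float)
    if slab.size == 0:
        raise ValueError("empty slab")
    sub = _pca_slab(slab)
    sub = sub - sub.mean(axis=0, keepdims=True)
    s = svd(sub, compute_uv=False)
    total = float(np.sum(s**2))
    if total == 0:
        return 1
    cum = np.cumsum(s**2) / total
    k = int(np.searchsorted(cum, ev_total) + 1)
    return min(k, k_max, len(s))


# ---------------------------------------------------------------------------
# tensor construction


def _int_shift(x: np.ndarray, s: int) -> np.ndarray:
    """Shift along axis 0 by s points, zero-filling (no wrap-around)."""
    out = np.zeros_like(x)
    if s == 0:
        out[:] = x
    elif s > 0:
        out[s:] = x[: x.shape[0] - s]
    else:
        out[:s] = x[-s:]
    return out


def _spectral_gate(slab: np.ndarray, spec: np.ndarray) -> np.ndarray:
    """Per-time weight: (positive Pearson r of each spectrum vs ``spec``)^4.

    Down-weights stretches of the window where a spectrally different
    compound elutes, leaving the reference compound's own elution region
    as the effective alignment support.
    """
    centered_spec = spec - spec.mean()
    n_spec = np.linalg.norm(centered_spec)
    rows = slab - slab.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(rows, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = (rows @ centered_spec) / (norms * n_spec)
    rho = np.nan_to_num(rho, nan=0.0)
    return np.clip(rho, 0.0, None) ** 4


def _best_shift_matched(source: np.ndarray, target: np.ndarray,
                        weights: np.ndarray, lags) -> int:
    """Shift of ``source`` best matching ``target`` under a weighted template fit.

    Maximizes <w*target, source_s> / ||source_s||_w over integer shifts.
    Unlike plain cross-correlation on a truncated (gated) support, this
    normalized criterion attains its maximum at the true shift when the
    gated stretch of the target is an exact scaled copy of the source
    (Cauchy-Schwarz equality), so a partially suppressed coeluting
    component does not bias the alignment.
    """
    n = source.size
    wt = weights * target
    best_s, best_score = 0, -np.inf
    for s in lags:
        if abs(s) >= n:
            continue
        src = _int_shift(source, s)
        den = float(np.sqrt(np.sum(weights * src * src)))
        if den <= 0:
            continue
        score = float(np.dot(wt, src)) / den
        if score > best_score:
            best_score, best_s = score, s
    return best_s


def _best_shift(ref_trace: np.ndarray, target_trace: np.ndarray) -> int:
    """Integer shift of ``ref_trace`` maximizing cross-correlation with target."""
    n = ref_trace.size
    c = np.correlate(target_trace, ref_trace, mode="full")
    lags = np.arange(-(n - 1), n)
    return int(lags[int(np.argmax(c))])


def build_tensor(impure_slab: np.ndarray,
                 reference_slabs: Sequence[np.ndarray],
                 reference_spectra: Optional[Sequence[np.ndarray]] = None,
                 base_shift: int = 0, max_refine: int = 0,
                 ) -> Tuple[np.ndarray, List[int]]:
    """Stack the impure window with aligned reference windows.

    Slab 0 is the impure sample; slabs 1..m are pure reference windows
    of candidate library compounds, shifted along time to align with the
    impure window.  Without ``reference_spectra`` the shift is the
    integer offset maximizing summed-trace cross-correlation over all
    lags.  With ``reference_spectra`` (unit spectra, one per reference)
    the time axis is taken as already anchored by the campaign's
    retention correction: the known residual shift ``base_shift`` is
    applied as-is (``max_refine`` = 0), optionally refined within
    ``+-max_refine`` points using a spectrally gated, normalized matched
    filter for campaigns with residual drift.  A free-running search is
    deliberately avoided there — under coelution any matrix-based
    alignment criterion is biased toward the coeluting impurity's mass
    (non-negative spectra always overlap), which detaches the reference
    from its own compound in the fit.
    Returns the (time, wavelength, slab) tensor and the applied shifts.
    """
    impure_slab = np.asarray(impure_slab, dtype=float)
    slabs = [impure_slab]
    shifts = [0]
    for i, ref in enumerate(reference_slabs):
        ref = np.asarray(ref, dtype=float)
        if ref.shape != impure_slab.shape:
            raise ValueError(
                f"reference slab shape {ref.shape} does not match impure "
                f"slab {impure_slab.shape}"
            )
        if reference_spectra is not None:
            spec = np.asarray(reference_spectra[i], dtype=float)
            target = np.clip(impure_slab @ spec, 0.0, None)
            weights = _spectral_gate(impure_slab, spec)
            source = np.clip(ref @ spec, 0.0, None)
            lags = range(base_shift - max_refine, base_shift + max_refine + 1)
            s = _best_shift_matched(source, target, weights, lags)
        else:
            target = impure_slab.sum(axis=1)
            source = ref.sum(axis=1)
            s = _best_shift(source, target)
        slabs.append(_int_shift(ref, s))
        shifts.append(s)
    tensor = np.stack(slabs, axis=-1)
    return tensor, shifts


# ---------------------------------------------------------------------------
# non-negative PARAFAC by multi-restart alternating least squares


@dataclass
class ParafacResult:
    """Best non-negative CP model of a window tensor."""

    elutions: np.ndarray      # (n_time, k), unit-norm columns
    spectra: np.ndarray       # (n_wavelength, k), unit-norm columns
    loadings: np.ndarray      # (n_slab, k), carries magnitude
    loss_history: np.ndarray  # squared reconstruction error per iteration
    converged: bool
    relative_loss: float      # final loss / ||tensor||^2

    @property
    def k(self) -> int:
        return self.elutions.shape[1]


def _unfold(X: np.ndarray, mode: int) -> np.ndarray:
    return np.moveaxis(X, mode, 0).reshape(X.shape[mode], -1)


def _khatri_rao(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    k = A.shape[1]
    return (A[:, None, :] * B[None, :, :]).reshape(-1, k)


def _svd_init(X: np.ndarray, k: int, rng: np.random.Generator):
    factors = []
    for mode in range(3):
        unf = _unfold(X, mode)
        u, s, _ = svd(unf, full_matrices=False)
        r = min(k, u.shape[1])
        f = np.abs(u[:, :r])
        if r < k:
            f = np.hstack([f, rng.random((f.shape[0], k - r))])
        factors.append(np.ascontiguousarray(f) + 1e-12)
    return factors


def _hals_run(X, factors, tol, max_iter):
    """HALS non-negative ALS; returns factors, loss history, converged."""
    unfolds = [_unfold(X, m) for m in range(3)]
    norm_x2 = float(np.sum(X**2))
    losses = []
    prev = np.inf
    converged = False
    A, B, C = factors
    for _ in range(max_iter):
        for mode, (U, V, W) in ((0, (A, B, C)), (1, (B, A, C)), (2, (C, A, B))):
            G = (V.T @ V) * (W.T @ W)
            M = unfolds[mode] @ _khatri_rao(V, W)
            for r in range(U.shape[1]):
                denom = G[r, r]
                if denom < 1e-300:
                    U[:, r] = 1e-12
                    continue
                col = U[:, r] + (M[:, r] - U @ G[:, r]) / denom
                np.clip(col, 0.0, None, out=col)
                if not col.any():
                    col[:] = 1e-12  # keep the component alive
                U[:, r] = col
        # loss via the Gram identity: ||X - recon||^2
        G_full = (A.T @ A) * (B.T @ B) * (C.T @ C)
        M3 = _unfold(X, 2) @ _khatri_rao(A, B)
        loss = norm_x2 - 2.0 * float(np.sum(M3 * C)) + float(np.sum(G_full))
        loss = max(loss, 0.0)
        losses.append(loss)
        if prev < np.inf:
            denom = max(prev, 1e-300)
            if abs(prev - loss) / denom < tol:
                converged = True
                break
        prev = loss
    return (A, B, C), np.asarray(losses), converged


def parafac_nnls(tensor: np.ndarray, k: int, tol: float = 1e-8,
                 max_iter: int = 500, restarts: int = 10,
                 seed: int = 0) -> ParafacResult:
    """Rank-k non-negative PARAFAC of a (time, wavelength, slab) tensor.

    Alternating non-negative least squares (HALS updates) minimizing the
    squared reconstruction error; the best of ``restarts`` seeded random
    initializations plus one SVD-based initialization is kept.  Elution
    and spectrum factors are returned unit-norm with all magnitude in the
    slab loadings.  The per-iteration loss is non-increasing within each
    run.

    Raises
    ------
    ValueError
        If k exceeds the time or wavelength dimension.  (The slab
        dimension does not bound the CP rank: a single-slab tensor is an
        ordinary non-negative matrix factorization of the window.)
    DeconvolutionError
        If every restart yields a non-finite model.
    """
    X = np.asarray(tensor, dtype=float)
    if X.ndim != 3:
        raise ValueError("tensor must be 3-way")
    if not np.all(np.isfinite(X)):
        raise ValueError("tensor contains non-finite values")
    if k < 1 or k > min(X.shape[0], X.shape[1]):
        raise ValueError(
            f"component count k={k} outside [1, min(time, wavelength) "
            f"= {min(X.shape[0], X.shape[1])}]"
        )
    rng = np.random.default_rng(seed)
    scale = float(np.abs(X).mean()) or 1.0
    inits = [_svd_init(X, k, rng)]
    for _ in range(restarts):
        inits.append([rng.random((dim, k)) * scale for dim in X.shape])

    best = None
    for factors in inits:
        factors = [np.ascontiguousarray(f, dtype=float) for f in factors]
        (A, B, C), losses, conv = _hals_run(X, factors, tol, max_iter)
        if not all(np.all(np.isfinite(f)) for f in (A, B, C)):
            continue
        final = losses[-1] if losses.size else np.inf
        if best is None or final < best[3]:
            best = ((A, B, C), losses, conv, final)
    if best is None:
        raise DeconvolutionError("all PARAFAC restarts produced non-finite factors")

    (A, B, C), losses, converged, final = best
    # scale normalization: unit-norm elution and spectrum, magnitude in loadings
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    A = A / na
    B = B / nb
    C = C * (na * nb)
    norm_x2 = float(np.sum(X**2)) or 1.0
    return ParafacResult(elutions=A, spectra=B, loadings=C,
                         loss_history=losses, converged=converged,
                         relative_loss=final / norm_x2)


# ---------------------------------------------------------------------------
# deconvolution pipeline


@dataclass
class DeconvComponent:
    """One resolved component of an impure peak window."""

    spectrum: Spectrum
    elution: np.ndarray         # non-negative shape over the window
    sample_loadings: np.ndarray # per-slab weights, slab 0 = impure sample
    integral: float             # mAU*min attributed in the impure sample
    assignment: Optional[str] = None
    match_r: float = 0.0
    concentration: Optional[float] = None

    def __post_init__(self):
        if np.any(self.elution < -1e-9) or np.any(self.sample_loadings < -1e-9):
            raise ValueError("negative elution or loadings")
        if self.integral < 0:
            raise ValueError("negative integral")
        if not -1.0 <= self.match_r <= 1.0:
            raise ValueError("match_r outside [-1, 1]")


def deconvolve(chrom: Chromatogram, peak: Peak, library,
               match_r_min: float = 0.90, ev_total: float = 0.995,
               k_max: int = 4, tol: float = 1e-8, max_iter: int = 500,
               restarts: int = 10, seed: int = 0,
               rt_shift: float = 0.0) -> List[DeconvComponent]:
    """Resolve an impure peak window into spectral components.

    Pipeline: estimate the component count by PCA, stack the window with
    aligned reference windows of library compounds whose retention time
    falls inside the window, fit non-negative PARAFAC, anchor component
    integrals to the window's summed-trace integral, and assign each
    component to the best-matching library spectrum (Pearson r >=
    ``match_r_min``; at most one component per compound, higher r wins).
    Unassigned components get stable per-window labels for the campaign
    registry to resolve.

    ``library`` is any object with an ``entries`` mapping of compound id
    to entries carrying ``spectrum``, ``ref_time`` and
    ``reference_chrom`` (a pure run on the same grids).  ``rt_shift`` is
    the run's retention-time correction in minutes (reference time minus
    observed time, from the internal standard); it anchors reference
    alignment.
    """
    sl = slice(peak.left_index, peak.right_index + 1)
    slab = chrom.absorbance[sl]
    k = estimate_component_count(slab, ev_total=ev_total, k_max=k_max)

    t_lo = chrom.time[peak.left_index] + rt_shift
    t_hi = chrom.time[peak.right_index] + rt_shift
    ref_entries = []
    ref_slabs = []
    entries = getattr(library, "entries", {}) or {}
    for cid, entry in entries.items():
        if entry.reference_chrom is None:
            continue
        if t_lo <= entry.ref_time <= t_hi:
            ref_entries.append(cid)
            ref_slabs.append(entry.reference_chrom.absorbance[sl])

    ref_spectra = [entries[cid].spectrum.values for cid in ref_entries]
    base_shift = int(round(-rt_shift / chrom.dt))
    tensor, _shifts = build_tensor(slab, ref_slabs, ref_spectra or None,
                                   base_shift=base_shift)
    k = max(1, min(k, tensor.shape[0], tensor.shape[1]))
    result = parafac_nnls(tensor, k, tol=tol, max_iter=max_iter,
                          restarts=restarts, seed=seed)

    dt = chrom.dt
    window_trace = slab.sum(axis=1)
    window_area = float(np.trapezoid(window_trace, dx=dt))

    raw_areas = np.empty(result.k)
    for r in range(result.k):
        raw_areas[r] = (result.loadings[0, r]
                        * float(np.trapezoid(result.elutions[:, r], dx=dt))
                        * float(result.spectra[:, r].sum()))
    total = raw_areas.sum()
    if total <= 0:
        raise DeconvolutionError("deconvolution attributed no area to the window")
    areas = raw_areas * (window_area / total)

    components: List[DeconvComponent] = []
    for r in range(result.k):
        try:
            spec = Spectrum(chrom.wavelength, result.spectra[:, r],
                            source="deconvolved")
        except ValueError:
            continue  # degenerate all-zero component
        components.append(DeconvComponent(
            spectrum=spec, elution=result.elutions[:, r].copy(),
            sample_loadings=result.loadings[:, r].copy(),
            integral=float(max(areas[r], 0.0)),
            assignment=f"component_{r}",
        ))

    # best-match assignment, at most one component per library compound
    proposals = []
    for idx, comp in enumerate(components):
        for cid, entry in entries.items():
            try:
                r_val = pearson_similarity(comp.spectrum, entry.spectrum)
            except ValueError:
                continue
            if r_val >= match_r_min:
                proposals.append((r_val, idx, cid))
    proposals.sort(reverse=True)
    used_components: set = set()
    used_compounds: set = set()
    for r_val, idx, cid in proposals:
        if idx in used_components or cid in used_compounds:
            continue
        components[idx].assignment = cid
        components[idx].match_r = r_val
        used_components.add(idx)
        used_compounds.add(cid)
    return components
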