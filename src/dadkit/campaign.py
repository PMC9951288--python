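"""Campaign orchestration: libraries, calibration, assignment, quantification.

A campaign processes runs in registration order.  Calibration runs build
the compound library (reference spectrum, retention time, calibration
points); sample runs are peak-picked, purity-checked, deconvolved where
impure, retention-corrected against the internal standard, assigned
against the library, and quantified through linear through-origin
calibration curves (absolute, or relative to the internal standard).
Unknown signals receive campaign-stable identifiers so the same impurity
can be tracked across runs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .config import Config
from .io import Chromatogram
from .peaks import (Peak, expand_borders, integrate, merge_overlapping,
                    pick_peaks, summed_trace, tag_apex_heights)
from .preprocess import correct_baseline, estimate_noise, trim_wavelengths
from .purity import (DeconvolutionError, Spectrum, check_purity, deconvolve,
                     pearson_similarity, spectrum_at)

logger = logging.getLogger(__name__)

__all__ = ["CompoundEntry", "CompoundLibrary", "QuantCurve", "RunRecord",
           "CampaignResult", "Campaign", "fit_quant_curve", "quantify_peak"]


@dataclass
class CompoundEntry:
    """Library entry for one calibrated compound."""

    compound_id: str
    spectrum: Spectrum
    ref_time: float
    istd: bool = False
    # (area, concentration, istd_area, istd_concentration)
    calibration_points: List[tuple] = field(default_factory=list)
    reference_chrom: Optional[Chromatogram] = None
    _spectra: List[np.ndarray] = field(default_factory=list)
    _times: List[float] = field(default_factory=list)


@dataclass
class CompoundLibrary:
    """All calibrated compounds of a campaign."""

    entries: Dict[str, CompoundEntry] = field(default_factory=dict)

    @property
    def istd_entry(self) -> Optional[CompoundEntry]:
        for entry in self.entries.values():
            if entry.istd:
                return entry
        return None


@dataclass(frozen=True)
class QuantCurve:
    """Linear through-origin calibration: area (or area ratio) vs concentration."""

    compound_id: str
    mode: str                 # "absolute" | "relative"
    slope: float
    r_squared: float
    n_points: int
    intercept: float = 0.0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError("calibration slope must be positive")
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("r_squared outside [0, 1]")


@dataclass
class RunRecord:
    """Processed outcome of one run."""

    run_id: str
    run_type: str
    peaks: List[Peak] = field(default_factory=list)
    rt_shift: float = 0.0
    istd_area: Optional[float] = None
    flags: List[str] = field(default_factory=list)


@dataclass
class CampaignResult:
    """Library, per-run records, and the long-format results table."""

    library: CompoundLibrary
    records: List[RunRecord]
    table: pd.DataFrame


def fit_quant_curve(entry: CompoundEntry, mode: str = "absolute") -> QuantCurve:
    """Least-squares through-origin calibration fit for one compound.

    Absolute mode regresses area on concentration; relative mode
    regresses area/istd_area on concentration/istd_concentration.
    ``r_squared`` is computed about the through-origin fit
    (1 - SS_res / sum(y^2)).  Non-positive areas are dropped with a
    warning.
    """
    xs, ys = [], []
    for point in entry.calibration_points:
        area, conc, istd_area, istd_conc = point
        if area is None or area <= 0:
            warnings.warn(
                f"{entry.compound_id}: dropping calibration point with "
                f"non-positive area {area!r}")
            continue
        if mode == "absolute":
            xs.append(conc)
            ys.append(area)
        elif mode == "relative":
            if not istd_area or not istd_conc:
                warnings.warn(
                    f"{entry.compound_id}: dropping calibration point without "
                    "internal-standard area")
                continue
            xs.append(conc / istd_conc)
            ys.append(area / istd_area)
        else:
            raise ValueError(f"unknown quantification mode {mode!r}")
    if not xs:
        raise ValueError(f"{entry.compound_id}: no usable calibration points")
    x = np.asarray(xs)
    y = np.asarray(ys)
    slope = float((x @ y) / (x @ x))
    ss_res = float(np.sum((y - slope * x) ** 2))
    ss_tot = float(np.sum(y**2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return QuantCurve(compound_id=entry.compound_id, mode=mode, slope=slope,
                      r_squared=float(np.clip(r2, 0.0, 1.0)), n_points=len(xs))


def quantify_peak(area: float, curve: QuantCurve,
                  istd_area: Optional[float] = None,
                  istd_concentration: Optional[float] = None) -> float:
    """Concentration from an integrated area through a calibration curve."""
    if curve.mode == "absolute":
        return area / curve.slope
    if istd_area is None or istd_area <= 0:
        raise ValueError("relative quantification requires a positive istd area")
    if istd_concentration is None:
        raise ValueError("relative quantification requires the run's istd concentration")
    return (area / istd_area) / curve.slope * istd_concentration


class Campaign:
    """Ordered collection of runs sharing a method, library and config."""

    def __init__(self, config: Optional[Config] = None,
                 quant_mode: str = "absolute"):
        self.config = config or Config()
        if quant_mode not in ("absolute", "relative"):
            raise ValueError(f"unknown quantification mode {quant_mode!r}")
        self.quant_mode = quant_mode
        self.runs: List[Chromatogram] = []
        self.library = CompoundLibrary()
        self.curves: Dict[str, QuantCurve] = {}
        self.records: List[RunRecord] = []
        self._run_ids: set = set()
        self._unknowns: List[tuple] = []  # (id, Spectrum, rt)

    # -- registration --------------------------------------------------

    def register_run(self, chrom: Chromatogram) -> None:
        meta = chrom.meta
        if not meta.run_id:
            raise ValueError("run has no id")
        if meta.run_id in self._run_ids:
            raise ValueError(f"duplicate run id {meta.run_id!r}")
        if meta.run_type == "calibration":
            if meta.compound is None:
                raise ValueError(f"calibration run {meta.run_id!r} declares no compound")
            if meta.concentration is None:
                raise ValueError(
                    f"calibration run {meta.run_id!r} declares no concentration")
        self._run_ids.add(meta.run_id)
        self.runs.append(chrom)

    # -- shared per-run processing --------------------------------------

    def _preprocess(self, chrom: Chromatogram) -> Chromatogram:
        wl = self.config.wavelength
        if wl.min is not None or wl.max is not None:
            lo = wl.min if wl.min is not None else chrom.wavelength[0]
            hi = wl.max if wl.max is not None else chrom.wavelength[-1]
            chrom = trim_wavelengths(chrom, lo, hi)
        b = self.config.baseline
        return correct_baseline(chrom, b.smoothness, b.asymmetry, b.iterations)

    def _detect(self, chrom: Chromatogram):
        trace = summed_trace(chrom)
        noise = estimate_noise(trace)
        pk_cfg = self.config.peaks
        peaks = pick_peaks(trace, noise, pk_cfg.rel_height, pk_cfg.snr_min,
                           run_id=chrom.meta.run_id)
        tag_apex_heights(trace, peaks)
        for i, peak in enumerate(peaks):
            left_limit = peaks[i - 1].apex_index + 1 if i > 0 else 0
            right_limit = (peaks[i + 1].apex_index - 1
                           if i < len(peaks) - 1 else trace.size - 1)
            expand_borders(trace, peak, noise, left_limit, right_limit)
        peaks = merge_overlapping(peaks)
        for peak in peaks:
            peak.integral = integrate(trace, peak, chrom.dt)
            window = chrom.absorbance[peak.left_index : peak.right_index + 1]
            peak.saturated = bool(np.any(window > pk_cfg.saturation_mau))
        return trace, noise, peaks

    def _check_purity(self, chrom: Chromatogram, peaks: List[Peak]) -> None:
        p_cfg = self.config.purity
        for peak in peaks:
            try:
                report = check_purity(chrom, peak, p_cfg.r_min, p_cfg.ev_min)
                peak.purity = report
                peak.pure = report.pure
            except ValueError:
                # too narrow to judge; treat as pure, skip deconvolution
                peak.pure = True

    # -- library building ------------------------------------------------

    def _process_calibration(self, chrom: Chromatogram) -> RunRecord:
        meta = chrom.meta
        pre = self._preprocess(chrom)
        trace, noise, peaks = self._detect(pre)
        self._check_purity(pre, peaks)
        record = RunRecord(run_id=meta.run_id, run_type="calibration", peaks=peaks)

        istd_entry = self.library.istd_entry
        candidates = []
        for peak in peaks:
            if not peak.pure or peak.saturated:
                continue
            spec = spectrum_at(pre, peak.apex_index)
            if (istd_entry is not None and not meta.istd
                    and pearson_similarity(spec, istd_entry.spectrum) >= 0.95):
                continue  # the internal standard's own peak
            candidates.append((peak.integral, peak, spec))
        if not candidates:
            raise ValueError(
                f"calibration run {meta.run_id!r}: no pure, unsaturated peak "
                f"to assign to {meta.compound!r}")
        _, peak, spec = max(candidates, key=lambda c: c[0])
        peak.assignment = meta.compound

        entry = self.library.entries.get(meta.compound)
        apex_time = float(pre.time[peak.apex_index])
        if entry is None:
            entry = CompoundEntry(compound_id=meta.compound, spectrum=spec,
                                  ref_time=apex_time, istd=meta.istd)
            self.library.entries[meta.compound] = entry
        entry._spectra.append(spec.values)
        entry._times.append(apex_time)
        entry.spectrum = Spectrum(pre.wavelength,
                                  np.mean(entry._spectra, axis=0),
                                  source="library")
        entry.ref_time = float(np.median(entry._times))
        if (entry.reference_chrom is None
                or peak.integral > getattr(entry, "_ref_area", -np.inf)):
            entry.reference_chrom = pre
            entry._ref_area = peak.integral  # type: ignore[attr-defined]

        istd_area = istd_conc = None
        if istd_entry is not None and not meta.istd:
            found = self._find_istd_peak(pre, peaks, istd_entry)
            if found is not None:
                istd_area = found.integral
                istd_conc = meta.istd_concentration
        entry.calibration_points.append(
            (peak.integral, meta.concentration, istd_area, istd_conc))
        self.curves.pop(meta.compound, None)  # refit lazily
        return record

    def build_library(self) -> CompoundLibrary:
        """Process all registered calibration runs into the library."""
        # internal-standard calibrations first so other runs can exclude it
        cal = [r for r in self.runs if r.meta.run_type == "calibration"]
        if not cal:
            raise ValueError("no calibration runs registered")
        for chrom in sorted(cal, key=lambda c: not c.meta.istd):
            self.records.append(self._process_calibration(chrom))
        return self.library

    # -- sample processing -----------------------------------------------

    def _find_istd_peak(self, chrom, peaks, istd_entry) -> Optional[Peak]:
        best = None
        for peak in peaks:
            t = float(chrom.time[peak.apex_index])
            if abs(t - istd_entry.ref_time) > 0.5:
                continue
            try:
                r = pearson_similarity(spectrum_at(chrom, peak.apex_index),
                                       istd_entry.spectrum)
            except ValueError:
                continue
            if r >= 0.95 and (best is None or r > best[0]):
                best = (r, peak)
        return best[1] if best else None

    def correct_retention(self, peaks: List[Peak], chrom: Chromatogram) -> float:
        """Retention shift (minutes) from the internal-standard peak."""
        istd_entry = self.library.istd_entry
        if istd_entry is None:
            return 0.0
        found = self._find_istd_peak(chrom, peaks, istd_entry)
        if found is None:
            raise ValueError(
                f"run {chrom.meta.run_id!r}: internal standard not found")
        return istd_entry.ref_time - float(chrom.time[found.apex_index])

    def _unknown_id(self, spec: Spectrum, rt: float) -> str:
        a_cfg = self.config.assign
        best = None
        for uid, uspec, urt in self._unknowns:
            if abs(urt - rt) > a_cfg.rt_window:
                continue
            try:
                r = pearson_similarity(spec, uspec)
            except ValueError:
                continue
            if r >= a_cfg.spec_r_min and (best is None or r > best[0]):
                best = (r, uid)
        if best is not None:
            return best[1]
        uid = f"unknown_{len(self._unknowns) + 1:03d}"
        self._unknowns.append((uid, spec, rt))
        return uid

    def assign_peaks(self, chrom: Chromatogram, peaks: List[Peak],
                     rt_shift: float = 0.0) -> None:
        """Assign pure peaks and deconvolved components against the library."""
        a_cfg = self.config.assign
        claims: Dict[str, tuple] = {}  # compound -> (r, rt_dev, peak)
        pending_unknown: List[tuple] = []
        for peak in peaks:
            if not peak.pure:
                continue
            t = float(chrom.time[peak.apex_index]) + rt_shift
            try:
                spec = spectrum_at(chrom, peak.apex_index)
            except ValueError:
                continue
            best = None
            for cid, entry in self.library.entries.items():
                if abs(t - entry.ref_time) > a_cfg.rt_window:
                    continue
                try:
                    r = pearson_similarity(spec, entry.spectrum)
                except ValueError:
                    continue
                if r >= a_cfg.spec_r_min and (best is None or r > best[0]):
                    best = (r, cid)
            if best is None:
                pending_unknown.append((peak, spec, t))
                continue
            r, cid = best
            rt_dev = abs(t - self.library.entries[cid].ref_time)
            incumbent = claims.get(cid)
            if incumbent is None or (r, -rt_dev) > (incumbent[0], -incumbent[1]):
                if incumbent is not None:
                    logger.warning("run %s: peak conflict on %s; demoting weaker match",
                                   chrom.meta.run_id, cid)
                    pending_unknown.append((incumbent[2], incumbent[3], incumbent[4]))
                claims[cid] = (r, rt_dev, peak, spec, t)
            else:
                logger.warning("run %s: peak conflict on %s; demoting weaker match",
                               chrom.meta.run_id, cid)
                pending_unknown.append((peak, spec, t))
        for cid, (r, _dev, peak, _spec, _t) in claims.items():
            peak.assignment = cid
        for peak, spec, t in pending_unknown:
            peak.assignment = self._unknown_id(spec, t)

    def _curve_for(self, cid: str) -> Optional[QuantCurve]:
        if cid in self.curves:
            return self.curves[cid]
        entry = self.library.entries.get(cid)
        if entry is None or not entry.calibration_points:
            return None
        mode = self.quant_mode
        if entry.istd:
            mode = "absolute"  # the istd itself is calibrated absolutely
        try:
            curve = fit_quant_curve(entry, mode)
        except ValueError:
            return None
        self.curves[cid] = curve
        return curve

    def process_run(self, chrom: Chromatogram) -> RunRecord:
        """Full pipeline for one sample/blank/simulation run."""
        meta = chrom.meta
        pre = self._preprocess(chrom)
        trace, noise, peaks = self._detect(pre)
        record = RunRecord(run_id=meta.run_id, run_type=meta.run_type, peaks=peaks)
        if not peaks:
            return record
        self._check_purity(pre, peaks)

        # retention correction first: it anchors reference alignment in
        # the deconvolution step as well as peak matching
        rt_shift = 0.0
        if self.library.istd_entry is not None:
            try:
                rt_shift = self.correct_retention(peaks, pre)
            except ValueError as exc:
                logger.warning(str(exc))
                record.flags.append("istd_missing")
        record.rt_shift = rt_shift

        d_cfg = self.config.deconv
        for peak in peaks:
            if peak.pure is False:
                try:
                    peak.components = deconvolve(
                        pre, peak, self.library,
                        match_r_min=d_cfg.match_r_min, k_max=d_cfg.k_max,
                        tol=d_cfg.tol, max_iter=d_cfg.max_iter,
                        restarts=d_cfg.restarts, seed=d_cfg.seed,
                        rt_shift=rt_shift)
                except (DeconvolutionError, ValueError) as exc:
                    logger.warning("run %s: deconvolution failed: %s",
                                   meta.run_id, exc)
                    record.flags.append("deconvolution_failed")
                    peak.components = []

        self.assign_peaks(pre, peaks, rt_shift)
        # stable unknown ids for deconvolved components
        for peak in peaks:
            t = float(pre.time[peak.apex_index]) + rt_shift
            for comp in peak.components:
                if comp.assignment is None or comp.assignment.startswith("component_"):
                    comp.assignment = self._unknown_id(comp.spectrum, t)

        istd_entry = self.library.istd_entry
        istd_area = None
        if istd_entry is not None:
            found = self._find_istd_peak(pre, peaks, istd_entry)
            if found is not None:
                istd_area = found.integral
                record.istd_area = istd_area

        for peak in peaks:
            targets = [(peak, peak.integral)] if peak.pure else []
            targets += [(c, c.integral) for c in peak.components]
            for obj, area in targets:
                cid = obj.assignment
                curve = self._curve_for(cid) if cid else None
                if curve is None:
                    continue
                try:
                    obj.concentration = quantify_peak(
                        area, curve, istd_area, meta.istd_concentration)
                except ValueError:
                    record.flags.append(f"unquantified:{cid}")
        return record

    # -- campaign-level --------------------------------------------------

    def process_campaign(self) -> CampaignResult:
        """Process all registered runs in order and emit the results table."""
        self.records = []
        processed_cal = False
        cal = [r for r in self.runs if r.meta.run_type == "calibration"]
        others = [r for r in self.runs if r.meta.run_type != "calibration"]
        if cal:
            self.build_library()
            processed_cal = True
        for chrom in others:
            record = self.process_run(chrom)
            if not processed_cal:
                record.flags.append("no_calibration")
            self.records.append(record)
        return CampaignResult(library=self.library, records=self.records,
                              table=self.results_table())

    def results_table(self) -> pd.DataFrame:
        """Long-format table: one row per peak plus one per deconvolved component."""
        rows = []
        for record in self.records:
            chrom = next(c for c in self.runs if c.meta.run_id == record.run_id)
            for i, peak in enumerate(record.peaks):
                rt = float(chrom.time[min(peak.apex_index, chrom.n_time - 1)])
                rows.append({
                    "run": record.run_id, "peak": i, "component": "window",
                    "compound": peak.assignment,
                    "retention_time": rt + record.rt_shift,
                    "area": peak.integral, "concentration": peak.concentration,
                    "pure": peak.pure, "saturated": peak.saturated,
                    "deconvolved": bool(peak.components),
                    "flags": ";".join(record.flags),
                })
                for j, comp in enumerate(peak.components):
                    rows.append({
                        "run": record.run_id, "peak": i, "component": f"c{j}",
                        "compound": comp.assignment,
                        "retention_time": rt + record.rt_shift,
                        "area": comp.integral,
                        "concentration": comp.concentration,
                        "pure": False, "saturated": peak.saturated,
                        "deconvolved": True, "flags": ";".join(record.flags),
                    })
        columns = ["run", "peak", "component", "compound", "retention_time",
                   "area", "concentration", "pure", "saturated", "deconvolved",
                   "flags"]
        return pd.DataFrame(rows, columns=columns)
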