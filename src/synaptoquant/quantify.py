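"""Calibrated quantification of synaptic transfer.

This is the core chain: gate single cells and single bead-supported lipid
bilayers (BSLBs) out of a co-culture acquisition, compute background-corrected
geometric mean fluorescence (cGMFI), convert to absolute molecules per event
through an MESF bead calibration and the detection antibody's F/P ratio, and
express transfer as NST% (share of total signal on the BSLB), Tmax% (percent
of the reference-series maximum) and molecular surface densities.

The calibration follows the standard MESF procedure: a ladder of beads with
known Molecules of Equivalent Soluble Fluorochrome is acquired, cGMFI is
regressed on MESF, and the fitted line converts a sample cGMFI into
fluorochromes per event; dividing by the antibody's fluorophore-to-protein
ratio gives bound antibodies, i.e. molecules.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter1d

from .io import AntibodyPanel, EventTable

__all__ = [
    "Geometry",
    "GateConfig",
    "GateResult",
    "CalibrationCurve",
    "gate_singlets",
    "gmfi",
    "correct_gmfi",
    "fit_mesf",
    "molecules_per_event",
    "nst_percent",
    "tmax_percent",
    "density",
    "quantify_coculture",
]

#: customary acquisition floor: single BSLBs recorded per condition
ACQUISITION_FLOOR = 50_000


@dataclass(frozen=True)
class Geometry:
    """Bead and vesicle-patch geometry used for density estimates.

    The BSLB is a 5.00 µm silica bead, so its surface area is
    π·d² ≈ 78.54 µm²; the vesicle "stamp" patch area of 0.82 µm² converts
    molecules per deposited patch into an effective patch density.
    """

    bead_diameter_um: float = 5.00
    patch_area_um2: float = 0.82

    def __post_init__(self):
        if self.bead_diameter_um <= 0 or self.patch_area_um2 <= 0:
            raise ValueError("geometry must be strictly positive")

    @property
    def bead_surface_area_um2(self) -> float:
        return math.pi * self.bead_diameter_um ** 2


# ---------------------------------------------------------------------------
# gating
# ---------------------------------------------------------------------------


@dataclass
class GateConfig:
    """Thresholds for singlet gating; ``None`` means derive from the data.

    BSLBs carry a fluorescent lipid dye, so lipid-positive events are bilayer
    particles and lipid-negative events are cells; conjugate doublets are
    lipid-positive with roughly the summed scatter of a cell and a bead.
    """

    lipid_channel: str = "LIPID"
    fsc_channel: str = "FSC"
    debris_fsc: float = 1500.0
    lipid_threshold: float | None = None    # auto: valley between the lipid modes
    doublet_fsc: float | None = None        # auto: doublet_ratio x median bead FSC
    doublet_ratio: float = 2.5
    calibration_acquisition: bool = False
    min_events: int = ACQUISITION_FLOOR


@dataclass
class GateResult:
    """Per-event classification and the thresholds that produced it."""

    classes: pd.Series                      # one of the five event classes
    params: dict[str, float] = field(default_factory=dict)

    CLASSES = ("single_cell", "single_BSLB", "doublet", "debris", "calibration_bead")

    def counts(self) -> dict[str, int]:
        vc = self.classes.value_counts()
        return {c: int(vc.get(c, 0)) for c in self.CLASSES}

    def mask(self, cls: str) -> np.ndarray:
        return (self.classes == cls).to_numpy()


def _valley(values: np.ndarray, bins: int = 128, smooth: float = 3.0) -> float | None:
    """Threshold at the deepest valley between the two main modes of log10(x).

    Returns ``None`` when the distribution looks unimodal.
    """
    x = np.log10(np.clip(values, 1e-9, None))
    hist, edges = np.histogram(x, bins=bins)
    smoothed = gaussian_filter1d(hist.astype(float), smooth)
    # boundary bins count as peaks so near-noiseless delta clusters are found
    padded = np.concatenate([[-np.inf], smoothed, [-np.inf]])
    peaks = [i for i in range(bins)
             if padded[i + 1] >= padded[i] and padded[i + 1] > padded[i + 2]]
    if len(peaks) < 2:
        return None
    peaks.sort(key=lambda i: smoothed[i], reverse=True)
    a, b = sorted(peaks[:2])
    if a == b:
        return None
    valley_idx = a + int(np.argmin(smoothed[a:b + 1]))
    centers = 0.5 * (edges[:-1] + edges[1:])
    return float(10 ** centers[valley_idx])


def gate_singlets(events: EventTable, config: GateConfig | None = None) -> GateResult:
    """Classify events as single cell / single BSLB / doublet / debris.

    Debris is everything below the forward-scatter floor.  Among the rest,
    the lipid-dye channel separates bilayer particles from cells, and a
    forward-scatter threshold separates single BSLBs from cell:BSLB doublets.
    Thresholds are taken from the config when set and otherwise derived by
    valley detection between intensity modes, so a re-run with the same
    thresholds reproduces the same partition exactly.
    """
    config = config or GateConfig()
    if config.lipid_channel not in events.channels:
        raise ValueError(f"no lipid channel {config.lipid_channel!r} in event table")
    if config.fsc_channel not in events.scatter:
        raise ValueError(f"no scatter channel {config.fsc_channel!r} in event table")
    fsc = events.intensity(config.fsc_channel)
    lipid = events.intensity(config.lipid_channel)
    n = len(events)

    classes = np.full(n, "debris", dtype=object)
    live = fsc >= config.debris_fsc

    if config.calibration_acquisition:
        classes[live] = "calibration_bead"
    elif live.any():
        t_lipid = config.lipid_threshold
        if t_lipid is None:
            t_lipid = _valley(lipid[live])
            if t_lipid is None:  # single lipid mode: call everything by its side
                t_lipid = float(np.sqrt(np.median(lipid[live]) * 4 * np.max(lipid[live])))
        lipid_pos = live & (lipid > t_lipid)
        classes[live & ~lipid_pos] = "single_cell"
        if lipid_pos.any():
            t_doublet = config.doublet_fsc
            if t_doublet is None:
                t_doublet = config.doublet_ratio * float(np.median(fsc[lipid_pos]))
            classes[lipid_pos & (fsc <= t_doublet)] = "single_BSLB"
            classes[lipid_pos & (fsc > t_doublet)] = "doublet"

    result = GateResult(pd.Series(classes, name="gate_class"),
                        {"debris_fsc": config.debris_fsc})
    counts = result.counts()
    if not live.any():
        warnings.warn("all events classified as debris", stacklevel=2)
    for cls in ("single_cell", "single_BSLB"):
        if not config.calibration_acquisition and 0 < counts[cls] < config.min_events:
            warnings.warn(
                f"only {counts[cls]} {cls} events; below the {config.min_events} "
                f"single-BSLB acquisition floor convention", stacklevel=2)
    return result


# ---------------------------------------------------------------------------
# GMFI and background correction
# ---------------------------------------------------------------------------


def gmfi(intensities, return_excluded: bool = False):
    """Geometric mean fluorescence intensity of the strictly positive events.

    Non-positive events (possible after compensation) are excluded; their
    count is available via ``return_excluded``.  Raises if no positive events
    remain, since the geometric mean is then undefined.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size == 0:
        raise ValueError("gmfi of an empty vector is undefined")
    pos = x[x > 0]
    excluded = int(x.size - pos.size)
    if pos.size == 0:
        raise ValueError("gmfi undefined: no strictly positive events")
    value = float(np.exp(np.mean(np.log(pos))))
    return (value, excluded) if return_excluded else value


def correct_gmfi(sample_gmfi: float, control_gmfi: float) -> tuple[float, float]:
    """Background-corrected GMFI: sample minus isotype/antigen-null control.

    Returns ``(cgmfi, raw_difference)``: the corrected value is floored at 0
    for use inside ratio statistics, while the raw (possibly negative)
    difference is retained for the record.
    """
    if not (np.isfinite(sample_gmfi) and np.isfinite(control_gmfi)):
        raise ValueError("GMFI values must be finite")
    if sample_gmfi < 0 or control_gmfi < 0:
        raise ValueError("GMFI values must be non-negative")
    raw = sample_gmfi - control_gmfi
    return max(raw, 0.0), raw


# ---------------------------------------------------------------------------
# MESF calibration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear map from MESF to cGMFI (slope in cGMFI per fluorochrome).

    The inverse map converts a sample cGMFI into fluorochromes per event:
    ``(cgmfi - intercept) / slope``.
    """

    slope: float
    intercept: float
    r_squared: float
    levels: tuple[float, ...]
    n_excluded: int = 0

    def __post_init__(self):
        if self.slope <= 0:
            raise ValueError(f"calibration failure: non-positive slope {self.slope:g}")
        if len(self.levels) < 2:
            raise ValueError("calibration needs at least two MESF levels")

    @classmethod
    def from_points(cls, levels, cgmfi, through_origin: bool = True) -> "CalibrationCurve":
        """Least-squares line of per-level cGMFI on MESF.

        With ``through_origin`` (the default) only the slope is fitted: the
        blank subtraction already anchors zero, and a free intercept over
        log-spaced MESF levels is dominated by top-level noise, which then
        corrupts low-signal molecule estimates on the inverse map.  Set it
        False for a conventional free-intercept OLS.
        """
        levels = np.asarray(levels, dtype=float)
        cgmfi = np.asarray(cgmfi, dtype=float)
        if levels.size < 2:
            raise ValueError("need at least two MESF levels for a regression")
        if through_origin:
            slope = float(np.sum(levels * cgmfi) / np.sum(levels ** 2))
            rss = float(np.sum((cgmfi - slope * levels) ** 2))
            tss = float(np.sum((cgmfi - cgmfi.mean()) ** 2))
            r2 = 1.0 - rss / tss if tss > 0 else 1.0
            return cls(slope, 0.0, r2, tuple(levels))
        fit = stats.linregress(levels, cgmfi)
        return cls(float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2),
                   tuple(levels))

    def fluorochromes(self, cgmfi: float) -> float:
        """Fluorochromes per event; below-intercept values floor at 0 with a warning."""
        raw = (cgmfi - self.intercept) / self.slope
        if raw < 0:
            warnings.warn(
                f"cGMFI {cgmfi:g} below calibration intercept {self.intercept:g}; "
                f"extrapolating to 0 fluorochromes", stacklevel=2)
            return 0.0
        return raw


def fit_mesf(bead_events: EventTable, levels, channel: str | None = None,
             through_origin: bool = True) -> CalibrationCurve:
    """Fit the MESF calibration line from a labelled bead-ladder acquisition.

    Events must carry ``MESF_<level>`` labels (as written by the ladder
    simulator or an upstream gate).  A zero level, when present, serves as the
    blank whose GMFI is subtracted from every positive level's GMFI before
    the regression of cGMFI on MESF.
    """
    if bead_events.labels is None:
        raise ValueError("bead events must be labelled with their MESF level")
    levels = sorted(set(float(v) for v in levels))
    positive = [v for v in levels if v > 0]
    if len(positive) < 2:
        raise ValueError("need at least two positive MESF levels for a regression")
    per_level, excluded = {}, 0
    for level in levels:
        mask = (bead_events.labels == f"MESF_{level:g}").to_numpy()
        if not mask.any():
            raise ValueError(f"no events labelled for MESF level {level:g}")
        name = channel or bead_events.channels[0]
        value, n_exc = gmfi(bead_events.intensity(name)[mask], return_excluded=True)
        per_level[level] = value
        excluded += n_exc
    blank = per_level.get(0.0, 0.0)
    cgmfi = [correct_gmfi(per_level[v], blank)[0] for v in positive]
    curve = CalibrationCurve.from_points(positive, cgmfi, through_origin)
    return CalibrationCurve(curve.slope, curve.intercept, curve.r_squared,
                            tuple(positive), excluded)


def molecules_per_event(cgmfi: float, curve: CalibrationCurve, f_over_p: float) -> float:
    """Absolute molecules per event: fluorochromes / (F/P of the antibody)."""
    if f_over_p <= 0:
        raise ValueError("F/P ratio must be positive")
    return curve.fluorochromes(cgmfi) / f_over_p


# ---------------------------------------------------------------------------
# transfer statistics
# ---------------------------------------------------------------------------


def nst_percent(cgmfi_bslb: float, cgmfi_cell: float) -> float:
    """Normalized synaptic transfer: 100 · BSLB / (BSLB + cell) cGMFI."""
    if cgmfi_bslb < 0 or cgmfi_cell < 0:
        raise ValueError("cGMFI values must be non-negative")
    total = cgmfi_bslb + cgmfi_cell
    if total == 0:
        raise ValueError("NST% undefined when both cGMFI values are zero")
    return 100.0 * cgmfi_bslb / total


def tmax_percent(cgmfi_bslb: float, cgmfi_bslb_max: float) -> float:
    """Percent of the reference-series maximum: 100 · cGMFI / max cGMFI."""
    if cgmfi_bslb_max <= 0:
        raise ValueError("reference maximum must be positive")
    return 100.0 * cgmfi_bslb / cgmfi_bslb_max


def density(molecules: float, area_um2: float) -> float:
    """Molecular surface density in molec./µm²."""
    if area_um2 <= 0:
        raise ValueError("area must be positive")
    if molecules < 0:
        raise ValueError("molecule count must be non-negative")
    return molecules / area_um2


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------


def quantify_coculture(
    events: EventTable,
    panel: AntibodyPanel,
    curve: CalibrationCurve,
    geometry: Geometry | None = None,
    gate_config: GateConfig | None = None,
    tmax_reference: str | None = "self",
) -> pd.DataFrame:
    """Run the quantification chain over a multi-acquisition co-culture table.

    The event table must carry ``acquisition``, ``tcell_population`` and
    ``dose`` columns (as the simulator writes).  Background precedence: the
    isotype-control acquisition if present, else the population's
    antigen-null acquisition; with neither, this raises.  ``tmax_reference``
    names the series whose maximum cGMFI anchors Tmax%: ``"self"`` uses each
    marker x population series' own maximum, a population label uses that
    population's series, and ``None`` refuses (the reference must be an
    explicit choice).

    Returns one row per marker x dose x population with cGMFI pairs, absolute
    molecules per BSLB, NST%, Tmax% and bead/patch surface densities.
    """
    if tmax_reference is None:
        raise ValueError("tmax_reference must be declared ('self' or a population label)")
    geometry = geometry or Geometry()
    gate_config = gate_config or GateConfig()
    panel.validate_against(events)
    df = events.data
    for col in ("acquisition", "tcell_population", "dose"):
        if col not in df.columns:
            raise ValueError(f"event table lacks the {col!r} condition column")

    # gate every acquisition once
    class_gmfi: dict[tuple[str, str, str], float] = {}  # (acq, class, channel) -> GMFI
    acq_index: dict[str, tuple[str, float]] = {}
    for acq, block_idx in df.groupby("acquisition").groups.items():
        mask = np.zeros(len(df), dtype=bool)
        mask[np.asarray(block_idx)] = True
        block = events.subset(mask)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # acquisition-floor warnings handled upstream
            gate = gate_singlets(block, gate_config)
        sub = block.data
        acq_index[acq] = (str(sub["tcell_population"].iloc[0]),
                          float(sub["dose"].iloc[0]))
        for cls in ("single_cell", "single_BSLB"):
            sel = gate.mask(cls)
            if not sel.any():
                continue
            for ch in block.channels:
                class_gmfi[(acq, cls, ch)] = gmfi(block.intensity(ch)[sel])

    def control_gmfi(cls: str, channel: str, population: str) -> float:
        if ("isotype", cls, channel) in class_gmfi:
            return class_gmfi[("isotype", cls, channel)]
        key = (f"null:{population}", cls, channel)
        if key in class_gmfi:
            return class_gmfi[key]
        raise ValueError(
            f"no isotype or antigen-null control acquisition for channel {channel!r}")

    rows = []
    for acq, (population, dose) in sorted(acq_index.items()):
        if acq == "isotype" or acq.startswith("null:"):
            continue
        for marker, entry in panel.markers.items():
            ch = entry.channel
            if (acq, "single_BSLB", ch) not in class_gmfi:
                continue
            cg_bslb, raw_bslb = correct_gmfi(
                class_gmfi[(acq, "single_BSLB", ch)], control_gmfi("single_BSLB", ch, population))
            cg_cell, raw_cell = correct_gmfi(
                class_gmfi[(acq, "single_cell", ch)], control_gmfi("single_cell", ch, population))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mols = molecules_per_event(cg_bslb, curve, entry.f_over_p)
            rows.append({
                "marker": marker, "population": population, "dose": dose,
                "cGMFI_BSLB": cg_bslb, "cGMFI_cell": cg_cell,
                "raw_diff_BSLB": raw_bslb, "raw_diff_cell": raw_cell,
                "molecules_per_BSLB": mols,
                "nst_percent": (nst_percent(cg_bslb, cg_cell)
                                if cg_bslb + cg_cell > 0 else np.nan),
                "density_bead": density(mols, geometry.bead_surface_area_um2),
                "density_patch": density(mols, geometry.patch_area_um2),
            })
    records = pd.DataFrame(rows)
    if records.empty:
        raise ValueError("no quantifiable acquisitions found")

    # Tmax%: anchor each marker x population series to its declared reference
    tmax = np.full(len(records), np.nan)
    for marker, sub in records.groupby("marker"):
        for population in sub.population.unique():
            ref_pop = population if tmax_reference == "self" else tmax_reference
            ref = records[(records.marker == marker) & (records.population == ref_pop)]
            if ref.empty:
                raise ValueError(f"Tmax reference series {ref_pop!r} not present")
            ref_max = float(ref.cGMFI_BSLB.max())
            sel = (records.marker == marker) & (records.population == population)
            tmax[sel.to_numpy()] = [tmax_percent(v, ref_max)
                                    for v in records.loc[sel, "cGMFI_BSLB"]]
    records["tmax_percent"] = tmax
    return records.sort_values(["marker", "population", "dose"]).reset_index(drop=True)
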