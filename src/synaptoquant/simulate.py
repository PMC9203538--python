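"""Synthetic-data generator with known ground truth.

Every input the quantification pipeline consumes can be generated here:
MESF calibration-bead ladders, T-cell/BSLB co-culture acquisitions laid out as
2-fold surrogate-antigen titrations, nanoFCM vesicle scatter events, and
IRM/TIRF synapse image pairs.  All outputs are deterministic functions of
(design, seed), and each generator returns the ground truth it drew from, so
downstream estimates can be scored against known values.

Signal model
------------
Per-event fluorescence is multiplicative log-normal around a target geometric
mean: ``x = m * exp(sigma * Z)`` with ``sigma = sqrt(ln(1 + CV^2))``, so the
cluster geometric mean converges to ``m``.  For a BSLB in a co-culture the
target is ``background + gain * (F/P) * molecules``, where ``gain`` is the
instrument's arbitrary-units-per-fluorochrome constant (the same constant the
MESF ladder exposes) and molecules follow the population's four-parameter
logistic transfer curve at the given surrogate-antigen density.  Cells hold a
fixed molecule pool and lose what their BSLB gains, so the ground-truth NST%
is well defined from molecule counts alone.

Vesicle side scatter follows a fixed power law of diameter (exponent 4, a
small-particle scattering heuristic); the law's exact shape is immaterial
because the sizing module calibrates empirically against simulated standards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import EventTable

__all__ = [
    "MarkerSpec",
    "PopulationTruth",
    "SimulationDesign",
    "GroundTruth",
    "VesicleTruth",
    "ImageTruth",
    "four_param_logistic",
    "simulate_mesf_ladder",
    "simulate_coculture",
    "simulate_vesicle_population",
    "simulate_size_standards",
    "simulate_synapse_image",
    "DEFAULT_GAIN",
    "SCATTER_EXPONENT",
    "SCATTER_COEFF",
]

#: instrument gain, arbitrary fluorescence units per fluorochrome
DEFAULT_GAIN = 0.5

#: side-scatter power law for sub-micron particles: ssc = coeff * d^exponent
SCATTER_EXPONENT = 4.0
SCATTER_COEFF = 1e-5

# typical geometric means for the non-marker channels (arbitrary units)
_LIPID_CELL = 5.0
_LIPID_BSLB = 5000.0
_FSC = {"debris": 300.0, "bead": 10_000.0, "cell": 30_000.0}
_SSC = {"debris": 200.0, "bead": 8_000.0, "cell": 20_000.0}


def _sigma(cv: float) -> float:
    return float(np.sqrt(np.log1p(cv * cv)))


def _lognormal(rng: np.random.Generator, gm: np.ndarray | float, cv: float,
               size: int) -> np.ndarray:
    """Log-normal draws with geometric mean ``gm`` and coefficient of variation ``cv``."""
    if cv < 0:
        raise ValueError("CV must be non-negative")
    gm = np.broadcast_to(np.asarray(gm, dtype=float), (size,))
    if cv == 0:
        return gm.copy()
    return gm * np.exp(_sigma(cv) * rng.standard_normal(size))


def four_param_logistic(dose, bottom, top, ec50, hill):
    """Transfer at a surrogate-antigen density: bottom + (top-bottom)/(1+(EC50/dose)^hill).

    Dose 0 is evaluated as the lower asymptote (the null-antigen condition).
    """
    dose = np.asarray(dose, dtype=float)
    out = np.full(dose.shape, float(bottom))
    pos = dose > 0
    out[pos] = bottom + (top - bottom) / (1.0 + (ec50 / dose[pos]) ** hill)
    return out if out.shape else float(out)


@dataclass(frozen=True)
class MarkerSpec:
    """A detection antibody in the panel: channel, F/P ratio, background level."""

    channel: str
    f_over_p: float = 2.0
    background: float = 50.0  # arbitrary units, the isotype/null signal level

    def __post_init__(self):
        if self.f_over_p <= 0:
            raise ValueError("F/P must be positive")
        if self.background < 0:
            raise ValueError("background must be non-negative")


@dataclass(frozen=True)
class PopulationTruth:
    """Ground-truth transfer curve of one T-cell population.

    ``tmax_molecules`` is the plateau of molecules deposited per BSLB;
    ``pool_molecules`` is the cell's conserved marker pool (default twice the
    plateau, so NST% saturates at 50%).
    """

    tmax_molecules: float
    ec50: float
    hill: float = 1.2
    bottom: float = 0.0
    pool_molecules: float | None = None

    def molecules_at(self, dose: float) -> float:
        return float(four_param_logistic(
            np.asarray([dose]), self.bottom, self.tmax_molecules, self.ec50, self.hill)[0])

    @property
    def pool(self) -> float:
        return self.pool_molecules if self.pool_molecules is not None else 2.0 * self.tmax_molecules


def _default_doses() -> list[float]:
    # 2-fold titration of surrogate antigen, 0-1000 molec./um^2
    return [0.0] + [1000.0 / 2 ** k for k in reversed(range(8))]


def _default_populations() -> dict[str, PopulationTruth]:
    return {
        "TH": PopulationTruth(tmax_molecules=20_000, ec50=250.0, hill=1.2),
        "Treg": PopulationTruth(tmax_molecules=9_000, ec50=125.0, hill=1.1),
        "CTL": PopulationTruth(tmax_molecules=15_000, ec50=60.0, hill=1.3),
    }


@dataclass
class SimulationDesign:
    """Full description of a simulated co-culture experiment."""

    doses: list[float] = field(default_factory=_default_doses)
    populations: dict[str, PopulationTruth] = field(default_factory=_default_populations)
    markers: dict[str, MarkerSpec] = field(
        default_factory=lambda: {"CD40L": MarkerSpec(channel="AF647")})
    n_events_per_population: int = 10_000
    cv: float = 0.30
    doublet_fraction: float = 0.02
    gain: float = DEFAULT_GAIN
    spillover: np.ndarray | None = None  # optional square matrix over marker channels
    seed: int = 0

    def __post_init__(self):
        doses = np.asarray(self.doses, dtype=float)
        if np.any(doses < 0):
            raise ValueError("doses must be non-negative")
        if np.any(np.diff(doses) <= 0):
            raise ValueError("doses must be strictly increasing")
        if self.cv <= 0:
            raise ValueError("CV must be positive")
        if not 0 <= self.doublet_fraction < 1:
            raise ValueError("doublet fraction must be in [0, 1)")
        if self.n_events_per_population <= 0:
            raise ValueError("event counts must be positive")
        channels = {m.channel for m in self.markers.values()}
        if len(channels) != len(self.markers):
            raise ValueError("marker channels must be unique")


@dataclass
class GroundTruth:
    """True quantities behind a simulated co-culture.

    ``conditions`` has one row per population x dose x marker with the true
    molecules per BSLB, per cell, and NST%.  The transfer-curve parameters,
    gain and marker specs are kept so any stage of the pipeline can be scored.
    """

    conditions: pd.DataFrame
    populations: dict[str, PopulationTruth]
    markers: dict[str, MarkerSpec]
    gain: float

    def nst_percent(self, population: str, dose: float, marker: str) -> float:
        df = self.conditions
        row = df[(df.population == population) & (df.dose == dose) & (df.marker == marker)]
        return float(row.nst_percent.iloc[0])


# ---------------------------------------------------------------------------
# MESF ladder
# ---------------------------------------------------------------------------


def simulate_mesf_ladder(
    levels: list[float],
    n_events: int = 5000,
    cv: float = 0.30,
    seed: int = 0,
    gain: float = DEFAULT_GAIN,
    channel: str = "AF647",
    blank_level: float = 1.0,
) -> EventTable:
    """Simulate a multi-level MESF calibration-bead acquisition.

    One log-normal cluster per level; a positive level's geometric mean is
    ``gain * MESF`` and a zero level (blank beads) sits at ``blank_level``.
    Labels record the nominal MESF value of each event's cluster.
    """
    levels = sorted(set(float(v) for v in levels))
    if sum(v > 0 for v in levels) < 2:
        raise ValueError("need at least two distinct positive MESF levels for a regression")
    if any(v < 0 for v in levels):
        raise ValueError("MESF levels must be non-negative")
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for level in levels:
        gm = gain * level if level > 0 else blank_level
        frames.append(pd.DataFrame({
            channel: _lognormal(rng, gm, cv, n_events),
            "FSC": _lognormal(rng, _FSC["bead"], cv, n_events),
            "SSC": _lognormal(rng, _SSC["bead"], cv, n_events),
        }))
        labels.extend([f"MESF_{level:g}"] * n_events)
    data = pd.concat(frames, ignore_index=True)
    return EventTable(data, [channel], ["FSC", "SSC"], labels,
                      {"acquisition": "mesf_ladder", "gain": str(gain)})


# ---------------------------------------------------------------------------
# co-culture titration
# ---------------------------------------------------------------------------


def simulate_coculture(design: SimulationDesign) -> tuple[EventTable, GroundTruth]:
    """Simulate the full titration experiment plus control acquisitions.

    The returned table concatenates, per population x dose, single-cell and
    single-BSLB events and a small doublet admixture, followed by an
    isotype-control co-culture (background-only marker signal) and an
    antigen-null acquisition per population.  ``labels`` carry the true event
    class; the ``acquisition``, ``tcell_population`` and ``dose`` columns
    identify the condition.  Ground-truth molecule counts and NST% per
    condition come from the population's logistic transfer curve.
    """
    rng = np.random.default_rng(design.seed)
    marker_channels = [m.channel for m in design.markers.values()]
    all_channels = ["LIPID"] + marker_channels
    n = design.n_events_per_population
    n_doublets = int(round(design.doublet_fraction * n))

    frames: list[pd.DataFrame] = []
    labels: list[str] = []
    truth_rows: list[dict] = []

    def marker_gm(marker: MarkerSpec, molecules: float) -> float:
        return marker.background + design.gain * marker.f_over_p * molecules

    def draw_class(kind: str, size: int, molecules: dict[str, float]) -> pd.DataFrame:
        """One event class: kind in {cell, bead}; molecules per marker name."""
        cols = {
            "LIPID": _lognormal(rng, _LIPID_CELL if kind == "cell" else _LIPID_BSLB,
                                design.cv, size),
            "FSC": _lognormal(rng, _FSC[kind], design.cv, size),
            "SSC": _lognormal(rng, _SSC[kind], design.cv, size),
        }
        for name, spec in design.markers.items():
            cols[spec.channel] = _lognormal(rng, marker_gm(spec, molecules[name]),
                                            design.cv, size)
        return pd.DataFrame(cols)

    def emit(acq: str, population: str, dose: float,
             cell_mol: dict[str, float], bead_mol: dict[str, float],
             with_doublets: bool) -> None:
        cells = draw_class("cell", n, cell_mol)
        beads = draw_class("bead", n, bead_mol)
        parts = [cells, beads]
        tags = ["single_cell"] * n + ["single_BSLB"] * n
        if with_doublets and n_doublets:
            dc = draw_class("cell", n_doublets, cell_mol)
            db = draw_class("bead", n_doublets, bead_mol)
            parts.append(dc + db)  # conjugate: summed cell + bead event
            tags += ["doublet"] * n_doublets
        block = pd.concat(parts, ignore_index=True)
        block["acquisition"] = acq
        block["tcell_population"] = population
        block["dose"] = dose
        frames.append(block)
        labels.extend(tags)

    for pop_name, pop in design.populations.items():
        for dose in design.doses:
            cell_mol, bead_mol = {}, {}
            for mk_name in design.markers:
                transferred = pop.molecules_at(dose)
                bead_mol[mk_name] = transferred
                cell_mol[mk_name] = pop.pool - transferred
                truth_rows.append({
                    "population": pop_name, "dose": dose, "marker": mk_name,
                    "molecules_bslb": transferred,
                    "molecules_cell": pop.pool - transferred,
                    "nst_percent": 100.0 * transferred / pop.pool,
                })
            emit(f"{pop_name}:dose={dose:g}", pop_name, dose,
                 cell_mol, bead_mol, with_doublets=True)

    # isotype-control co-culture: marker channels at background only
    zero = {mk: 0.0 for mk in design.markers}
    emit("isotype", "control", float("nan"), zero, zero, with_doublets=False)
    # antigen-null BSLB per population (dose 0, no doublets): BSLB at background
    for pop_name, pop in design.populations.items():
        cell_mol = {mk: pop.pool - pop.molecules_at(0.0) for mk in design.markers}
        bead_mol = {mk: pop.molecules_at(0.0) for mk in design.markers}
        emit(f"null:{pop_name}", pop_name, 0.0, cell_mol, bead_mol, with_doublets=False)

    data = pd.concat(frames, ignore_index=True)
    if design.spillover is not None:
        spill = np.asarray(design.spillover, dtype=float)
        k = len(marker_channels)
        if spill.shape != (k, k):
            raise ValueError("spillover matrix must be square over the marker channels")
        mixed = (spill @ data[marker_channels].to_numpy().T).T
        data[marker_channels] = mixed

    table = EventTable(data, all_channels, ["FSC", "SSC"], labels,
                       {"acquisition": "coculture", "gain": str(design.gain)})
    truth = GroundTruth(pd.DataFrame(truth_rows), dict(design.populations),
                        dict(design.markers), design.gain)
    return table, truth


def simulate_dose_response_study(
    bottom: float = 0.0,
    top: float = 100.0,
    ec50: float = 50.0,
    hill: float = 1.0,
    doses: list[float] | None = None,
    n_donors: int = 10,
    cv: float = 0.10,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Donor-level transfer measurements along the 2-fold titration ladder.

    Each of ``n_donors`` donors contributes one measurement per dose; donor
    scatter is homoscedastic Gaussian with standard deviation ``cv * top``
    (about 10% of the plateau is typical donor-to-donor spread).  The
    homoscedastic model matches the assumptions of the unweighted
    extra-sum-of-squares F comparison downstream.  Returns flat
    ``(doses, responses)`` arrays ready for fitting.
    """
    if n_donors < 1:
        raise ValueError("need at least one donor")
    base = np.asarray(doses if doses is not None else _default_doses(), dtype=float)
    rng = np.random.default_rng(seed)
    d = np.repeat(base, n_donors)
    y = four_param_logistic(d, bottom, top, ec50, hill)
    y = y + cv * top * rng.standard_normal(d.size)
    return d, y


# ---------------------------------------------------------------------------
# nanoFCM vesicles
# ---------------------------------------------------------------------------


@dataclass
class VesicleTruth:
    """True per-event diameters behind a simulated vesicle acquisition."""

    diameters: np.ndarray
    mixture: list[tuple[float, float]]
    extrapolated: np.ndarray  # True where the component lies outside the standard span
    standard_span: tuple[float, float]


def _scatter_of_diameter(d: np.ndarray | float) -> np.ndarray:
    return SCATTER_COEFF * np.asarray(d, dtype=float) ** SCATTER_EXPONENT


def simulate_vesicle_population(
    mixture: list[tuple[float, float]],
    n_events: int = 10_000,
    cv: float = 0.15,
    seed: int = 0,
    standard_span: tuple[float, float] = (68.0, 155.0),
) -> tuple[EventTable, VesicleTruth]:
    """Simulate nanoFCM side-scatter events from a diameter mixture.

    ``mixture`` is a list of (diameter nm, weight); weights must sum to 1.
    Side scatter is the fixed power law of the true diameter with multiplicative
    log-normal noise.  Components outside the silica-standard span are flagged
    as extrapolation in the returned truth rather than refused — sub-68 nm
    vesicles are real and must be measurable, just visibly marked.
    """
    diams = np.array([d for d, _ in mixture], dtype=float)
    weights = np.array([w for _, w in mixture], dtype=float)
    if np.any(diams <= 0):
        raise ValueError("diameters must be positive")
    if not np.isclose(weights.sum(), 1.0, atol=1e-9):
        raise ValueError(f"mixture weights must sum to 1, got {weights.sum():g}")
    rng = np.random.default_rng(seed)
    component = rng.choice(len(diams), size=n_events, p=weights)
    true_d = diams[component]
    ssc = _lognormal(rng, _scatter_of_diameter(true_d), cv, n_events)
    lo, hi = standard_span
    extrapolated = (true_d < lo) | (true_d > hi)
    table = EventTable(pd.DataFrame({"SSC": ssc}), [], ["SSC"],
                       metadata={"acquisition": "vesicles"})
    return table, VesicleTruth(true_d, list(mixture), extrapolated, standard_span)


def simulate_size_standards(
    diameters: list[float] = (68.0, 91.0, 113.0, 155.0),
    n_events: int = 2000,
    cv: float = 0.05,
    seed: int = 0,
) -> EventTable:
    """Simulate a silica size-standard cocktail acquisition (one cluster per bead size)."""
    rng = np.random.default_rng(seed)
    frames, labels = [], []
    for d in diameters:
        frames.append(pd.DataFrame({
            "SSC": _lognormal(rng, float(_scatter_of_diameter(d)), cv, n_events)}))
        labels.extend([f"std_{d:g}nm"] * n_events)
    return EventTable(pd.concat(frames, ignore_index=True), [], ["SSC"], labels,
                      {"acquisition": "size_standards"})


# ---------------------------------------------------------------------------
# synapse images
# ---------------------------------------------------------------------------


@dataclass
class ImageTruth:
    """Ground truth for a simulated IRM/TIRF image pair."""

    label_mask: np.ndarray          # int array, 0 = background, 1..n = contacts
    centers: list[tuple[int, int]]
    radii: list[float]
    intensities: list[float]
    background: float

    def integrated(self, index: int) -> float:
        """True background-subtracted integral of one contact (1-based index)."""
        area = int(np.sum(self.label_mask == index))
        return area * self.intensities[index - 1]


#: reflection-channel levels: bright field with dark contact footprints
_REFLECTION_BG = 30_000.0
_REFLECTION_CONTACT = 12_000.0


def simulate_synapse_image(
    n_contacts: int,
    radii: list[float] | float = 12.0,
    intensities: list[float] | float = 2000.0,
    background: float = 200.0,
    noise_sd: float = 20.0,
    seed: int = 0,
    shape: tuple[int, int] = (256, 256),
    centers: list[tuple[int, int]] | None = None,
) -> tuple[np.ndarray, np.ndarray, ImageTruth]:
    """Simulate an IRM reflection / TIRF fluorescence image pair.

    Contacts are non-overlapping disks: dark in the reflection channel, of
    uniform per-contact intensity above a flat background in the fluorescence
    channel, both with additive Gaussian noise of the given standard
    deviation.  Centers are placed by seeded rejection sampling unless given;
    overlapping or out-of-frame contacts are refused because the ground-truth
    masks would be ambiguous.
    """
    radii = list(np.broadcast_to(radii, n_contacts).astype(float))
    intensities = list(np.broadcast_to(intensities, n_contacts).astype(float))
    rng = np.random.default_rng(seed)
    h, w = shape

    def ok(c, r, placed):
        (y, x) = c
        if not (r <= y <= h - 1 - r and r <= x <= w - 1 - r):
            return False
        return all(np.hypot(y - py, x - px) > r + pr + 2 for (py, px), pr in placed)

    placed: list[tuple[tuple[int, int], float]] = []
    if centers is not None:
        if len(centers) != n_contacts:
            raise ValueError("need one center per contact")
        for c, r in zip(centers, radii):
            if not ok(c, r, placed):
                raise ValueError(f"contact at {c} overlaps another contact or the frame edge")
            placed.append((tuple(c), r))
    else:
        for r in radii:
            for _ in range(10_000):
                c = (int(rng.integers(0, h)), int(rng.integers(0, w)))
                if ok(c, r, placed):
                    placed.append((c, r))
                    break
            else:
                raise ValueError("could not place non-overlapping contacts; "
                                 "reduce n_contacts or radii")

    yy, xx = np.mgrid[0:h, 0:w]
    label = np.zeros(shape, dtype=np.int32)
    for i, ((cy, cx), r) in enumerate(placed, start=1):
        label[(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = i

    fluor = np.full(shape, background, dtype=float)
    refl = np.full(shape, _REFLECTION_BG, dtype=float)
    for i, inten in enumerate(intensities, start=1):
        fluor[label == i] += inten
        refl[label == i] = _REFLECTION_CONTACT
    if noise_sd > 0:
        fluor = fluor + noise_sd * rng.standard_normal(shape)
        refl = refl + noise_sd * rng.standard_normal(shape)

    truth = ImageTruth(label, [c for c, _ in placed], radii, intensities, background)
    return refl, fluor, truth
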