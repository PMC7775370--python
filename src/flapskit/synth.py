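"""Synthetic generators for every pipeline input, with known ground truth.

The generators emulate the observables of a fluorescently labeled
polysaccharide (FLA-PS) incubation experiment:

* time-resolved GPC chromatograms of a labeled substrate being depolymerized
  under an explicit chain-scission model (endo-acting random cleavage or
  exo-acting terminal monomer removal), with an exact record of cumulative
  cleavage events;
* paired two-channel epifluorescence scenes (DAPI / blue = all cells,
  FLA-PS 488 / green = substrate-stained "selfish" cells) with the true
  object table;
* sample x taxon amplicon count tables in which an initially rare
  opportunist (an *Alteromonas*-like taxon) blooms along a logistic curve;
* total cell count time series with logistic growth or exponential decline.

All randomness flows from the explicit ``seed`` argument of each call;
identical spec + seed gives bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .chrom import CalibrationCurve, fit_calibration, mw_of_dp

__all__ = [
    "SubstrateSpec", "KineticsSpec", "ImageSceneSpec", "CommunitySpec",
    "GrowthDynamics", "ChromatogramSeries", "ChromatogramTruth", "ImageScene",
    "CellCountSeries", "SUBSTRATE_NAMES", "default_calibration",
    "generate_chromatogram_series", "generate_image_scene", "generate_fov_set",
    "generate_community_series", "generate_cellcount_series",
]

#: The six polysaccharides used in the incubations.
SUBSTRATE_NAMES = ("pullulan", "laminarin", "xylan", "fucoidan",
                   "arabinogalactan", "chondroitin")


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubstrateSpec:
    """A labeled polysaccharide added to an incubation.

    ``monomer_conc`` is the added concentration in nmol monomer L^-1;
    the default 3500 is the 3.5 uM monosaccharide-equivalent addition used
    throughout the incubations.
    """

    name: str
    parent_dp: int
    monomer_conc: float = 3500.0

    def __post_init__(self):
        if self.parent_dp < 2:
            raise ValueError("parent_dp must be >= 2")
        if self.monomer_conc <= 0:
            raise ValueError("monomer_conc must be positive")


@dataclass(frozen=True)
class KineticsSpec:
    """Ground-truth cleavage kinetics for one incubation.

    ``cleavage_rate`` is per-linkage (endo_random) or per-chain-end
    (exo_monomer) cleavage probability per hour. ``killed=True`` models the
    autoclaved-seawater control: no enzymatic activity regardless of rate.
    """

    mechanism: str = "endo_random"
    cleavage_rate: float = 0.0
    killed: bool = False

    _MECHANISMS = ("endo_random", "exo_monomer", "none")

    def __post_init__(self):
        if self.mechanism not in self._MECHANISMS:
            raise ValueError(f"mechanism must be one of {self._MECHANISMS}")
        if self.cleavage_rate < 0:
            raise ValueError("cleavage_rate must be >= 0")

    @property
    def effective_rate(self) -> float:
        if self.killed or self.mechanism == "none":
            return 0.0
        return self.cleavage_rate


@dataclass(frozen=True)
class ImageSceneSpec:
    """One epifluorescence field of view (FOV) of DAPI-stained cells.

    ``pixel_pitch`` of 0.1 um/px makes 1 pixel = 0.01 um^2, so the fixed
    17-30 pixel window for substrate staining equals 0.17-0.3 um^2.
    ``fla_label_area_range`` is the nominal (pre-blur) green disc area;
    rendered labels are concentric with, and smaller than, their cell.
    """

    n_cells: int = 50
    selfish_fraction: float = 0.3
    pixel_pitch: float = 0.1
    fov_shape: tuple[int, int] = (512, 512)
    cell_area_range: tuple[float, float] = (0.25, 0.6)
    fla_label_area_range: tuple[float, float] = (0.20, 0.26)
    dapi_sbr: float = 5.0
    fla_sbr: float = 5.0
    background_level: float = 100.0
    background_noise_sd: float = 0.05
    n_fov: int = 36

    def __post_init__(self):
        if not 0.0 <= self.selfish_fraction <= 1.0:
            raise ValueError("selfish_fraction must be in [0, 1]")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel_pitch must be positive")
        if self.n_fov < 1:
            raise ValueError("n_fov must be >= 1")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        lo, hi = self.cell_area_range
        if not 0 < lo < hi:
            raise ValueError("cell_area_range must be a non-empty positive interval")
        if lo / self.pixel_pitch ** 2 < 4:
            raise ValueError("cell_area_range not representable at pixel_pitch "
                             "(< 4 pixels per cell)")
        if self.dapi_sbr <= 1 or self.fla_sbr <= 1:
            raise ValueError("signal-to-background ratios must exceed 1")


@dataclass(frozen=True)
class CommunitySpec:
    """An amplicon count-table time series with one blooming opportunist.

    The bloom taxon's expected relative abundance follows
    ``plateau / (1 + exp(-steepness * (day - midpoint)))`` on top of its
    baseline share; the remaining mass is split among all taxa in proportion
    to ``baseline_weights``. Read depths are lognormal with median
    ``read_depth_median`` (default 65,000), clipped at 1,000 reads.
    """

    n_taxa: int = 30
    baseline_weights: tuple[float, ...] = ()
    bloom_taxon: int = -1
    bloom_midpoint_d: float = 2.0
    bloom_steepness: float = 2.0
    bloom_plateau: float = 0.65
    read_depth_median: float = 65000.0
    read_depth_log_sd: float = 0.4
    read_depth_min: int = 1000
    dirichlet_concentration: float = 500.0
    timepoints_d: tuple[float, ...] = (0.0, 3.0, 6.0, 9.0, 12.0, 18.0)
    n_replicates: int = 1
    station: str = "Stn8"
    substrate: str = "laminarin"

    def __post_init__(self):
        if self.n_taxa < 2:
            raise ValueError("n_taxa must be >= 2")
        if not 0.0 <= self.bloom_plateau < 1.0:
            raise ValueError("bloom plateau must be in [0, 1)")
        if not len(self.baseline_weights):
            # power-law ranked baseline; the bloom taxon starts rare
            w = 1.0 / np.arange(1, self.n_taxa + 1, dtype=float)
            object.__setattr__(self, "baseline_weights", tuple(w))
        w = np.asarray(self.baseline_weights, dtype=float)
        if len(w) != self.n_taxa or np.any(w < 0) or w.sum() <= 0:
            raise ValueError("baseline_weights must be n_taxa non-negative values "
                             "with positive sum")
        if self.bloom_taxon == -1:
            object.__setattr__(self, "bloom_taxon", self.n_taxa - 1)
        if not 0 <= self.bloom_taxon < self.n_taxa:
            raise ValueError("bloom_taxon index out of range")
        for name in ("bloom_midpoint_d", "bloom_steepness"):
            if not np.isfinite(getattr(self, name)):
                raise ValueError(f"{name} must be finite")

    def taxon_names(self) -> list[str]:
        names = [f"taxon_{i:03d}" for i in range(self.n_taxa)]
        names[self.bloom_taxon] = "Alteromonas_like"
        return names

    def expected_proportions(self, day: float) -> np.ndarray:
        """Expected relative abundances at a given incubation day."""
        w = np.asarray(self.baseline_weights, dtype=float)
        base = w / w.sum()
        b = self.bloom_plateau / (1.0 + np.exp(
            -self.bloom_steepness * (day - self.bloom_midpoint_d)))
        p = (1.0 - b) * base
        p[self.bloom_taxon] += b
        return p


@dataclass(frozen=True)
class GrowthDynamics:
    """Deterministic mean cell-count dynamics for an incubation.

    kind 'logistic': growth from the initial count toward ``plateau`` at
    per-day rate ``rate_per_day``; kind 'decline': exponential relaxation
    toward ``floor``; kind 'constant': flat.
    """

    kind: str = "constant"
    rate_per_day: float = 0.0
    plateau: float = 0.0
    floor: float = 0.0

    def __post_init__(self):
        if self.kind not in ("logistic", "decline", "constant"):
            raise ValueError("kind must be logistic, decline or constant")
        if self.rate_per_day < 0:
            raise ValueError("rate_per_day must be >= 0")
        if self.kind == "logistic" and self.plateau <= 0:
            raise ValueError("logistic dynamics need a positive plateau")
        if self.kind == "decline" and self.floor < 0:
            raise ValueError("decline floor must be >= 0")

    def mean(self, initial: float, t_days) -> np.ndarray:
        t = np.asarray(t_days, dtype=float)
        if self.kind == "constant" or self.rate_per_day == 0.0:
            return np.full_like(t, initial)
        if self.kind == "logistic":
            k, n0 = self.plateau, initial
            return k / (1.0 + (k - n0) / n0 * np.exp(-self.rate_per_day * t))
        return self.floor + (initial - self.floor) * np.exp(-self.rate_per_day * t)


# ---------------------------------------------------------------------------
# Chromatograms
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChromatogramSeries:
    """Elution profiles of one incubation over its sampling timepoints."""

    sample_id: str
    substrate: str
    elution: np.ndarray
    timepoints_h: tuple[float, ...]
    signals: np.ndarray  # (n_timepoints, n_grid)

    def to_tsv(self, path) -> None:
        rows = []
        for i, t in enumerate(self.timepoints_h):
            rows.append(pd.DataFrame({
                "sample_id": self.sample_id, "substrate": self.substrate,
                "timepoint_h": t, "elution_position": self.elution,
                "signal": self.signals[i]}))
        pd.concat(rows, ignore_index=True).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> list["ChromatogramSeries"]:
        df = pd.read_csv(path, sep="\t")
        out = []
        for (sid, sub), g in df.groupby(["sample_id", "substrate"], sort=False):
            piv = g.pivot_table(index="timepoint_h", columns="elution_position",
                                values="signal", sort=True)
            out.append(cls(sample_id=str(sid), substrate=str(sub),
                           elution=piv.columns.to_numpy(dtype=float),
                           timepoints_h=tuple(float(t) for t in piv.index),
                           signals=piv.to_numpy(dtype=float)))
        return out


@dataclass(frozen=True)
class ChromatogramTruth:
    """Exact realized cleavage record for a generated chromatogram series."""

    seed: int
    n_chains: int
    parent_dp: int
    timepoints_h: tuple[float, ...]
    cleavages_per_monomer: tuple[float, ...]
    parent_mass_fraction: tuple[float, ...]

    def true_rate(self, monomer_conc: float) -> np.ndarray:
        """Ground-truth rate (nmol monomer L^-1 h^-1) vs t0 at each timepoint > 0."""
        t = np.asarray(self.timepoints_h[1:])
        c = np.asarray(self.cleavages_per_monomer[1:])
        return monomer_conc * c / t


def default_calibration(parent_dp: int, n_standards: int = 6) -> CalibrationCurve:
    """A GPC calibration spanning monomer to parent MW.

    Larger molecules elute earlier: elution runs linearly from 5.0 at the
    parent MW to 15.0 at the monomer MW on a log10(MW) axis.
    """
    mw_lo, mw_hi = float(mw_of_dp(1)), float(mw_of_dp(parent_dp))
    logs = np.linspace(np.log10(mw_lo), np.log10(mw_hi), n_standards)
    slope = (5.0 - 15.0) / (np.log10(mw_hi) - np.log10(mw_lo))
    elution = 15.0 + slope * (logs - np.log10(mw_lo))
    return fit_calibration(np.column_stack([10.0 ** logs, elution]))


def calibration_standards(calib: CalibrationCurve, n: int = 6) -> np.ndarray:
    """(MW_Da, elution) standard pairs sampled from a calibration curve."""
    mw = np.geomspace(calib.mw_min, calib.mw_max, n)
    return np.column_stack([mw, calib.elution_of_mw(mw)])


def _fragment_histogram(cut_mask: np.ndarray, parent_dp: int) -> np.ndarray:
    """DP histogram of fragments given per-chain linkage cut masks.

    ``cut_mask`` is (n_chains, parent_dp - 1) boolean; fragment lengths are
    run lengths between cut linkages (chain ends act as boundaries).
    """
    n = cut_mask.shape[0]
    bounds = np.ones((n, parent_dp), dtype=bool)
    bounds[:, :-1] = cut_mask
    pos = np.flatnonzero(bounds.ravel())
    lengths = np.diff(np.concatenate([[-1], pos]))
    return np.bincount(lengths, minlength=parent_dp + 1)


def _exo_histograms(n_events: np.ndarray, parent_dp: int) -> np.ndarray:
    """DP histogram for exo-acting removal: n monomers + one DP P-n remnant."""
    p = parent_dp
    hist = np.zeros(p + 1, dtype=np.int64)
    full = n_events >= p - 1
    hist[1] += int(np.minimum(n_events, p - 1)[~full].sum()) + int(full.sum()) * p
    remnants = p - n_events[~full]
    hist += np.bincount(remnants, minlength=p + 1)
    return hist


def generate_chromatogram_series(substrate: SubstrateSpec, kinetics: KineticsSpec,
                                 timepoints_h: Sequence[float],
                                 calib: CalibrationCurve | None = None,
                                 noise_sd: float = 0.0, seed: int = 0,
                                 n_chains: int = 2000, peak_sigma: float = 0.15,
                                 grid_step: float = 0.02,
                                 sample_id: str = "sample",
                                 ) -> tuple[ChromatogramSeries, ChromatogramTruth]:
    """Simulate GPC elution profiles of a depolymerizing labeled substrate.

    ``n_chains`` parent chains of DP ``substrate.parent_dp`` are tracked as
    integer DP multisets. Under ``endo_random`` each linkage carries an
    independent exponential cleavage clock at the per-linkage rate, so at
    time t every original linkage is cut with probability 1 - exp(-k t);
    under ``exo_monomer`` terminal monomers are removed at the per-end rate
    (two ends while DP > 2). Each DP class elutes as a Gaussian peak of
    constant width ``peak_sigma`` (elution units) centered at the calibrated
    position, with amplitude proportional to label mass (DP x chain count).

    ``noise_sd`` is additive Gaussian noise relative to the t0 peak height.
    Returns the series and the exact realized cleavage record.
    """
    t = np.asarray(timepoints_h, dtype=float)
    if len(t) < 1 or t[0] != 0.0:
        raise ValueError("timepoints must start at 0")
    if np.any(t < 0) or np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be non-negative and strictly increasing")
    if calib is None:
        calib = default_calibration(substrate.parent_dp)
    if not (calib.mw_min <= mw_of_dp(1) * (1 + 1e-9)
            and calib.mw_max >= mw_of_dp(substrate.parent_dp) * (1 - 1e-9)):
        raise ValueError("calibration does not span monomer to parent MW")

    p = substrate.parent_dp
    rng = np.random.default_rng(seed)
    k = kinetics.effective_rate

    hists = np.zeros((len(t), p + 1), dtype=np.int64)
    cuts = np.zeros(len(t), dtype=np.int64)
    if k == 0.0:
        hists[:, p] = n_chains
    elif kinetics.mechanism == "endo_random":
        cut_times = rng.exponential(1.0 / k, size=(n_chains, p - 1))
        for i, ti in enumerate(t):
            mask = cut_times <= ti
            hists[i] = _fragment_histogram(mask, p)
            cuts[i] = int(mask.sum())
    else:  # exo_monomer
        # step j removes a terminal monomer from a chain of DP p - j
        dp_now = p - np.arange(p - 1)
        scale = 1.0 / (k * np.where(dp_now >= 3, 2.0, 1.0))
        event_times = np.cumsum(rng.exponential(1.0, size=(n_chains, p - 1)) * scale,
                                axis=1)
        for i, ti in enumerate(t):
            n_events = (event_times <= ti).sum(axis=1)
            hists[i] = _exo_histograms(n_events, p)
            cuts[i] = int(n_events.sum())

    # render elution profiles
    lo, hi = calib.elution_range
    grid = np.arange(lo - 6 * peak_sigma, hi + 6 * peak_sigma + grid_step, grid_step)
    dp_axis = np.arange(1, p + 1)
    centers = calib.elution_of_mw(mw_of_dp(dp_axis))
    kernel = np.exp(-0.5 * ((grid[None, :] - centers[:, None]) / peak_sigma) ** 2)
    kernel /= peak_sigma * np.sqrt(2 * np.pi)
    total_mass = float(n_chains * p)
    signals = np.empty((len(t), len(grid)))
    for i in range(len(t)):
        mass = hists[i, 1:] * dp_axis / total_mass
        signals[i] = 100.0 * (mass @ kernel)
    peak0 = signals[0].max()
    if noise_sd > 0:
        signals = signals + rng.normal(0.0, noise_sd * peak0, size=signals.shape)

    series = ChromatogramSeries(sample_id=sample_id, substrate=substrate.name,
                                elution=grid, timepoints_h=tuple(t),
                                signals=signals)
    truth = ChromatogramTruth(seed=seed, n_chains=n_chains, parent_dp=p,
                              timepoints_h=tuple(t),
                              cleavages_per_monomer=tuple(cuts / total_mass),
                              parent_mass_fraction=tuple(hists[:, p] * p / total_mass))
    return series, truth


# ---------------------------------------------------------------------------
# Image scenes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ImageScene:
    """A paired DAPI (blue) / FLA-PS 488 (green) field of view with truth."""

    blue: np.ndarray   # uint16
    green: np.ndarray  # uint16
    pixel_pitch: float
    truth: pd.DataFrame  # object_id, row, col, area_um2, selfish, green_area_um2

    def save(self, directory, stem: str = "fov") -> None:
        """Write 16-bit TIFF pair, truth TSV and a pixel-pitch sidecar."""
        import tifffile
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        tifffile.imwrite(d / f"{stem}_dapi.tif", self.blue)
        tifffile.imwrite(d / f"{stem}_fla.tif", self.green)
        self.truth.to_csv(d / f"{stem}_truth.tsv", sep="\t", index=False)
        (d / f"{stem}_meta.tsv").write_text(
            f"pixel_pitch_um\t{self.pixel_pitch}\n")


def generate_image_scene(spec: ImageSceneSpec, seed: int = 0) -> ImageScene:
    """Render one synthetic two-channel FOV.

    Exactly ``spec.n_cells`` disjoint cells are placed (centers rejected
    until all pairwise disc separations hold); ``round(selfish_fraction *
    n_cells)`` of them receive a concentric, fully contained green label, so
    true blue/green overlap is 100% of the label area. Cells are filled
    discs convolved with a small Gaussian blur on a flat background with
    additive Gaussian noise.
    """
    rng = np.random.default_rng(seed)
    h, w = spec.fov_shape
    pp2 = spec.pixel_pitch ** 2

    areas = rng.uniform(*spec.cell_area_range, size=spec.n_cells)
    radii = np.sqrt(areas / pp2 / np.pi)
    margin = 5.0
    centers: list[tuple[float, float]] = []
    for i in range(spec.n_cells):
        placed = False
        for _ in range(500):
            r = radii[i]
            cy = rng.uniform(r + margin, h - r - margin)
            cx = rng.uniform(r + margin, w - r - margin)
            ok = all((cy - oy) ** 2 + (cx - ox) ** 2
                     >= (r + radii[j] + 6.0) ** 2
                     for j, (oy, ox) in enumerate(centers))
            if ok:
                centers.append((cy, cx))
                placed = True
                break
        if not placed:
            raise ValueError(
                f"could not place {spec.n_cells} non-overlapping cells of "
                f"area {spec.cell_area_range} um^2 in a {h}x{w} px FOV; "
                "reduce n_cells or the cell area")

    n_selfish = int(round(spec.selfish_fraction * spec.n_cells))
    selfish_idx = rng.choice(spec.n_cells, size=n_selfish, replace=False) \
        if n_selfish else np.array([], dtype=int)
    selfish = np.zeros(spec.n_cells, dtype=bool)
    selfish[selfish_idx] = True
    green_areas = np.full(spec.n_cells, np.nan)
    if n_selfish:
        lo, hi_a = spec.fla_label_area_range
        green_areas[selfish] = rng.uniform(lo, np.minimum(hi_a, areas[selfish]),
                                           size=n_selfish)

    bg = spec.background_level
    yy, xx = np.mgrid[0:h, 0:w]
    blue_fg = np.zeros((h, w))
    green_fg = np.zeros((h, w))
    for i, (cy, cx) in enumerate(centers):
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        blue_fg[d2 <= radii[i] ** 2] = (spec.dapi_sbr - 1.0) * bg
        if selfish[i]:
            rg = np.sqrt(green_areas[i] / pp2 / np.pi)
            green_fg[d2 <= rg ** 2] = (spec.fla_sbr - 1.0) * bg

    def finish(fg):
        img = bg + gaussian_filter(fg, sigma=0.6)
        img = img + rng.normal(0.0, spec.background_noise_sd * bg, size=fg.shape)
        return np.clip(np.round(img), 0, 65535).astype(np.uint16)

    truth = pd.DataFrame({
        "object_id": np.arange(spec.n_cells),
        "row": [c[0] for c in centers], "col": [c[1] for c in centers],
        "area_um2": areas, "selfish": selfish, "green_area_um2": green_areas})
    return ImageScene(blue=finish(blue_fg), green=finish(green_fg),
                      pixel_pitch=spec.pixel_pitch, truth=truth)


def generate_fov_set(spec: ImageSceneSpec, seed: int = 0) -> list[ImageScene]:
    """Generate ``spec.n_fov`` independent FOVs from one master seed."""
    rng = np.random.default_rng(seed)
    child = rng.integers(0, 2 ** 31 - 1, size=spec.n_fov)
    return [generate_image_scene(spec, seed=int(s)) for s in child]


# ---------------------------------------------------------------------------
# Community tables
# ---------------------------------------------------------------------------

def generate_community_series(spec: CommunitySpec, seed: int = 0,
                              forced_reads: dict[str, int] | None = None):
    """Draw a sample x taxon count table over the incubation timepoints.

    Counts follow a compound scheme: per-sample taxon proportions are drawn
    from a Dirichlet centered on the expected (logistic-bloom) composition,
    then reads are drawn multinomially at a lognormal read depth.
    ``forced_reads`` overrides the read depth of named samples (e.g. to
    emulate repeatedly sequenced low-yield samples under 10,000 reads).

    Returns ``(CommunityTable, truth)`` where truth is a DataFrame of
    expected proportions per timepoint.
    """
    from .community import CommunityTable

    rng = np.random.default_rng(seed)
    forced_reads = forced_reads or {}
    taxa = spec.taxon_names()
    rows, meta_rows, truth_rows = [], [], []
    for day in spec.timepoints_d:
        p = spec.expected_proportions(day)
        truth_rows.append(pd.Series(p, index=taxa, name=float(day)))
        for rep in range(1, spec.n_replicates + 1):
            sid = f"d{day:g}_r{rep}"
            if sid in forced_reads:
                reads = int(forced_reads[sid])
            else:
                depth = rng.lognormal(np.log(spec.read_depth_median),
                                      spec.read_depth_log_sd)
                reads = int(max(spec.read_depth_min, round(depth)))
            pi = rng.dirichlet(spec.dirichlet_concentration * p)
            counts = rng.multinomial(reads, pi)
            rows.append(pd.Series(counts, index=taxa, name=sid))
            meta_rows.append({"sample_id": sid, "station": spec.station,
                              "substrate": spec.substrate,
                              "timepoint_d": float(day), "replicate": rep,
                              "reads_total": int(counts.sum())})
    counts_df = pd.DataFrame(rows)
    counts_df.index.name = "sample_id"
    meta = pd.DataFrame(meta_rows).set_index("sample_id")
    truth = pd.DataFrame(truth_rows)
    truth.index.name = "timepoint_d"
    return CommunityTable(counts=counts_df, metadata=meta), truth


# ---------------------------------------------------------------------------
# Cell counts
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CellCountSeries:
    """Replicated total cell counts (cells ml^-1) over incubation days."""

    data: pd.DataFrame  # timepoint_d, replicate, cells_per_ml
    mean_curve: tuple[float, ...]
    timepoints_d: tuple[float, ...]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index=False)


def generate_cellcount_series(initial: float, dynamics: GrowthDynamics,
                              timepoints_d: Sequence[float],
                              noise_sd: float = 0.0, replicates: int = 3,
                              seed: int = 0) -> CellCountSeries:
    """Replicate cell-count series whose noiseless mean follows ``dynamics``.

    Observation noise is lognormal: counts are multiplied by
    ``exp(N(0, noise_sd))``; with ``noise_sd=0`` replicates equal the mean
    curve exactly.
    """
    if initial <= 0:
        raise ValueError("initial cell count must be positive")
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    t = np.asarray(timepoints_d, dtype=float)
    rng = np.random.default_rng(seed)
    mean = dynamics.mean(initial, t)
    rows = []
    for i, day in enumerate(t):
        mult = np.exp(rng.normal(0.0, noise_sd, size=replicates)) \
            if noise_sd > 0 else np.ones(replicates)
        for rep in range(replicates):
            rows.append({"timepoint_d": day, "replicate": rep + 1,
                         "cells_per_ml": mean[i] * mult[rep]})
    return CellCountSeries(data=pd.DataFrame(rows), mean_curve=tuple(mean),
                           timepoints_d=tuple(t))
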