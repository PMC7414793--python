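"""Ground-truth-known synthetic FLIM experiments.

Real NADH-FLIM datasets of microglial activation are not publicly
deposited, so every pipeline stage here is exercised on simulated
experiments whose group-level statistical structure reproduces published
group means: each *group preset* stores the mean lifetime tau_m (ps) and
free-NADH fraction a1 of one treatment condition and compartment,
together with the between-sample SD actually reported for it.  Presets
whose source prints no value for a field carry it from the matching
condition and are flagged ``assumed``.

Generative hierarchy (all draws Normal, truncated at physical bounds):

* replicate level — each biological sample i owns one standardized
  latent effect ``z_i``; its sample means are
  ``taum_i = mu + z_i * sd`` and ``a1_i = mu_a - z_i * sd_a`` (free
  fraction anticorrelated with lifetime).  In paired designs z_i is
  shared across treatment groups and compartments, encoding the
  within-replicate correlation a paired analysis implies while leaving
  every preset's marginal mean +/- SD exactly as printed.
* cell level — per-cell tau_m and a1 scatter around the sample means
  with coefficient of variation ``cell_cv`` (default 3%).
* pixel level — every pixel of a cell holds a Poisson realization of
  the cell's IRF-convolved bi-exponential decay scaled to
  ``photons_per_pixel`` expected photons.

The bound lifetime tau2 of each cell is derived from its (tau_m, a1)
via :func:`flimglia.decay_model.solve_tau2` at a fixed free lifetime
tau1 = 400 ps, so the printed group means are exact generative
parameters.  Scenes are non-overlapping elliptical somata; microglia
additionally grow short straight processes and are bright in the marker
channel.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import binary_dilation
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .decay_model import (
    AcquisitionGrid,
    BiExpParams,
    DomainError,
    IRFProfile,
    model_decay,
    solve_tau2,
)
from .segmentation import MarkerImage

__all__ = [
    "GroupPreset",
    "SceneGeometry",
    "CellScene",
    "ExperimentDesign",
    "PackingError",
    "PRESETS",
    "DEFAULT_TAU1",
    "make_scene",
    "sample_level_params",
    "draw_cell_params",
    "render_fov",
    "iter_fovs",
    "simulate_experiment",
]

DEFAULT_TAU1 = 400.0  # free-NADH lifetime (ps); literature-typical value

# Cell density at the reference 128 x 128 desk-scale field of view.
_REF_AREA = 128 * 128
_MICROGLIA_PER_REF = 20
_OTHER_PER_REF = 32


class PackingError(RuntimeError):
    """Requested cells could not be placed without overlap."""


@dataclass(frozen=True)
class GroupPreset:
    """Published group mean +/- between-sample SD for one compartment.

    ``a1`` values are fractions here (the analysis layer reports
    percent).  ``assumed`` names fields carried over from a matching
    condition because the source prints no value for them.
    """

    name: str
    taum_mean: float
    taum_sd: float
    a1_mean: float
    a1_sd: float
    compartment: str = "microglia"
    cell_cv: float = 0.03
    assumed: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.taum_mean <= 0 or self.taum_sd < 0 or self.a1_sd < 0:
            raise DomainError("preset means must be positive and SDs non-negative")
        if not 0.0 < self.a1_mean < 1.0:
            raise DomainError("a1_mean must lie in (0, 1)")
        if self.cell_cv < 0:
            raise DomainError("cell_cv must be >= 0")
        # the derived bound lifetime must be fittable
        tau2 = solve_tau2(self.taum_mean, self.a1_mean, DEFAULT_TAU1)
        if not 800.0 <= tau2 <= 6000.0:
            raise DomainError(
                f"preset {self.name!r}: derived tau2 {tau2:.0f} ps outside fit bounds"
            )


def _preset(name, taum, taum_sd, a1_pct, a1_sd_pct, compartment, assumed=()):
    return GroupPreset(
        name=name,
        taum_mean=taum,
        taum_sd=taum_sd,
        a1_mean=a1_pct / 100.0,
        a1_sd=a1_sd_pct / 100.0,
        compartment=compartment,
        assumed=tuple(assumed),
    )


def _pair(name, mg, nmg):
    mg = replace(mg, name=f"{name}/microglia", compartment="microglia")
    nmg = replace(nmg, name=f"{name}/non_microglia", compartment="non_microglia")
    return {"microglia": mg, "non_microglia": nmg}


# Published values (mean +/- between-sample SD; a1 in percent).
_MG = "microglia"
_NMG = "non_microglia"
_SURV_NMG = _preset("surv_nmg", 594.0, 23.3, 78.4, 1.4, _NMG)
_LPS_NMG = _preset("lps_nmg", 603.1, 27.4, 76.3, 1.5, _NMG)

PRESETS: dict[str, dict[str, GroupPreset]] = {
    # 1-h mixed glial culture, vehicle vs 10 ng/mL LPS
    "culture_vehicle_1h": _pair(
        "culture_vehicle_1h",
        _preset("v", 548.7, 19.4, 80.3, 0.85, _MG),
        replace(_SURV_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    "culture_LPS10_1h": _pair(
        "culture_LPS10_1h",
        _preset("l", 566.6, 28.8, 79.5, 1.1, _MG),
        _LPS_NMG,
    ),
    # surveillant panel: 10 samples, microglia vs other glia
    "culture_surveillant": _pair(
        "culture_surveillant",
        _preset("s", 558.8, 25.4, 81.1, 1.8, _MG),
        _SURV_NMG,
    ),
    # dose series (1 h)
    "dose_vehicle": _pair(
        "dose_vehicle",
        _preset("d0", 548.4, 19.1, 80.3, 0.9, _MG),
        replace(_SURV_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    "dose_LPS1": _pair(
        "dose_LPS1",
        _preset("d1", 540.2, 34.3, 80.2, 1.1, _MG),
        replace(_LPS_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    "dose_LPS10": _pair(
        "dose_LPS10",
        _preset("d10", 568.4, 28.5, 79.2, 1.2, _MG),
        replace(_LPS_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    "dose_LPS100": _pair(
        "dose_LPS100",
        _preset("d100", 578.4, 23.5, 79.8, 1.1, _MG),
        replace(_LPS_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    # time series (10 ng/mL LPS)
    "time_vehicle": _pair(
        "time_vehicle",
        _preset("t0", 570.5, 11.3, 80.9, 1.3, _MG),
        replace(_SURV_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    "time_LPS10_3h": _pair(
        "time_LPS10_3h",
        _preset("t3", 599.5, 10.2, 79.5, 0.2, _MG),
        replace(_LPS_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    "time_LPS10_8h": _pair(
        "time_LPS10_8h",
        _preset("t8", 616.4, 14.7, 79.01, 0.4, _MG),
        replace(_LPS_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    "time_LPS10_24h": _pair(
        "time_LPS10_24h",
        _preset("t24", 628.0, 8.0, 78.7, 0.2, _MG),
        replace(_LPS_NMG, assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd")),
    ),
    # ex vivo brain tissue (Iba1/A594-labelled microglia); tissue a1 values
    # are not printed and are carried from the matching culture condition
    "tissue_untreated": _pair(
        "tissue_untreated",
        _preset("tu", 751.6, 46.58, 80.3, 0.85, _MG, assumed=("a1_mean", "a1_sd")),
        _preset("tun", 778.6, 28.2, 78.4, 1.4, _NMG, assumed=("a1_mean", "a1_sd")),
    ),
    "tissue_LPS5mgkg": _pair(
        "tissue_LPS5mgkg",
        _preset("tl", 811.8, 23.7, 79.5, 1.1, _MG, assumed=("a1_mean", "a1_sd")),
        _preset(
            "tln", 778.6, 28.2, 76.3, 1.5, _NMG,
            assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd"),
        ),
    ),
    # CX3CR1-GFP tissue; non-microglia gets the untreated-tissue
    # compartment offset (+27.0 ps) applied to the GFP microglial mean
    "tissue_GFP_untreated": _pair(
        "tissue_GFP_untreated",
        _preset("gu", 668.42, 34.48, 80.3, 0.85, _MG, assumed=("a1_mean", "a1_sd")),
        _preset(
            "gun", 695.4, 28.2, 78.4, 1.4, _NMG,
            assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd"),
        ),
    ),
    "tissue_GFP_LPS": _pair(
        "tissue_GFP_LPS",
        _preset("gl", 683.16, 41.35, 79.5, 1.1, _MG, assumed=("a1_mean", "a1_sd")),
        _preset(
            "gln", 710.2, 28.2, 76.3, 1.5, _NMG,
            assumed=("taum_mean", "taum_sd", "a1_mean", "a1_sd"),
        ),
    ),
}


@dataclass(frozen=True)
class SceneGeometry:
    """Cell-placement parameters (pixels at desk scale, ~1.6 um/px)."""

    soma_radius: tuple[float, float] = (3.0, 5.0)
    n_processes: tuple[int, int] = (2, 3)  # microglia only
    process_length: tuple[int, int] = (3, 7)
    margin: int = 2  # minimum gap between somata (processes may approach)
    microglia_brightness: float = 1000.0
    other_brightness: float = 30.0
    max_attempts: int = 500


@dataclass
class CellScene:
    """Ground-truth label image with per-cell class and parameters."""

    labels: np.ndarray  # 0 = background, 1..n_cells otherwise
    classes: list[str]  # per cell: "microglia" | "other"
    marker_brightness: np.ndarray  # per cell
    cell_params: list[BiExpParams] | None = None

    @property
    def n_cells(self) -> int:
        return len(self.classes)

    def microglia_mask(self) -> np.ndarray:
        ids = np.flatnonzero(np.array(self.classes) == "microglia") + 1
        return np.isin(self.labels, ids)


@dataclass(frozen=True)
class ExperimentDesign:
    """One simulated experiment: groups x samples x FOVs.

    ``groups`` maps a group label to a preset name from :data:`PRESETS`.
    ``paired=True`` shares each replicate's latent effect across groups
    (split-culture / within-animal designs); cell counts default to a
    density of ~52 cells per 128 x 128 FOV, scaled by grid area.
    """

    groups: dict[str, str]
    n_samples: int = 5
    n_fovs: int = 20
    grid: AcquisitionGrid = field(default_factory=AcquisitionGrid)
    photons_per_pixel: float = 2000.0
    paired: bool = True
    seed: int = 0
    n_microglia: int | None = None
    n_other: int | None = None
    geometry: SceneGeometry = field(default_factory=SceneGeometry)
    marker_noise_sd: float = 20.0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise DomainError("n_samples must be >= 2")
        if self.n_fovs < 1:
            raise DomainError("n_fovs must be >= 1")
        for label, preset in self.groups.items():
            if preset not in PRESETS:
                raise DomainError(f"group {label!r}: unknown preset {preset!r}")

    def cells_per_fov(self) -> tuple[int, int]:
        area = self.grid.height * self.grid.width
        n_mg = self.n_microglia
        n_ot = self.n_other
        if n_mg is None:
            n_mg = max(1, round(_MICROGLIA_PER_REF * area / _REF_AREA))
        if n_ot is None:
            n_ot = max(1, round(_OTHER_PER_REF * area / _REF_AREA))
        return n_mg, n_ot


def make_scene(
    grid: AcquisitionGrid,
    n_microglia: int,
    n_other: int,
    geometry: SceneGeometry | None = None,
    rng: np.random.Generator | None = None,
) -> CellScene:
    """Place non-overlapping cells on the grid; deterministic per rng state.

    Microglia are ellipses with short straight processes; other cells are
    plain ellipses.  Cells keep ``geometry.margin`` pixels of clearance.
    Raises :class:`PackingError` when a cell cannot be placed within
    ``geometry.max_attempts`` tries.
    """
    geometry = geometry or SceneGeometry()
    rng = rng if rng is not None else np.random.default_rng()
    if n_microglia < 0 or n_other < 0:
        raise DomainError("cell counts must be >= 0")
    h, w = grid.height, grid.width
    labels = np.zeros((h, w), dtype=np.int32)
    blocked = np.zeros((h, w), dtype=bool)
    selem = disk(geometry.margin)
    classes = ["microglia"] * n_microglia + ["other"] * n_other
    brightness = np.empty(len(classes))
    r_lo, r_hi = geometry.soma_radius
    for i, cls in enumerate(classes):
        placed = False
        for _ in range(geometry.max_attempts):
            r1 = rng.uniform(r_lo, r_hi)
            r2 = rng.uniform(r_lo, r_hi)
            rot = rng.uniform(0.0, np.pi)
            margin_px = int(np.ceil(max(r1, r2))) + 1
            if cls == "microglia":
                margin_px += geometry.process_length[1]
            if 2 * margin_px >= min(h, w):
                raise PackingError("cells larger than the field of view")
            cy = rng.integers(margin_px, h - margin_px)
            cx = rng.integers(margin_px, w - margin_px)
            rr, cc = draw_ellipse(cy, cx, r1, r2, shape=(h, w), rotation=rot)
            soma = np.zeros((h, w), dtype=bool)
            soma[rr, cc] = True
            mask = soma.copy()
            if cls == "microglia":
                n_proc = rng.integers(
                    geometry.n_processes[0], geometry.n_processes[1] + 1
                )
                for _ in range(n_proc):
                    theta = rng.uniform(0.0, 2.0 * np.pi)
                    length = rng.integers(*geometry.process_length)
                    ey = int(np.clip(cy + (max(r1, r2) + length) * np.sin(theta), 0, h - 1))
                    ex = int(np.clip(cx + (max(r1, r2) + length) * np.cos(theta), 0, w - 1))
                    lr, lc = draw_line(int(cy), int(cx), ey, ex)
                    mask[lr, lc] = True
            if (blocked & mask).any() or (labels[mask] != 0).any():
                continue
            labels[mask] = i + 1
            # grow the blocked zone around the new soma only; processes
            # may interdigitate (as they do in tissue) but never overlap
            ys, xs = np.nonzero(soma)
            pad = geometry.margin + 1
            y0, y1 = max(ys.min() - pad, 0), min(ys.max() + pad + 1, h)
            x0, x1 = max(xs.min() - pad, 0), min(xs.max() + pad + 1, w)
            blocked[y0:y1, x0:x1] |= binary_dilation(soma[y0:y1, x0:x1], selem)
            placed = True
            break
        if not placed:
            raise PackingError(
                f"could not place cell {i + 1}/{len(classes)} after "
                f"{geometry.max_attempts} attempts"
            )
        if cls == "microglia":
            brightness[i] = geometry.microglia_brightness * rng.uniform(0.8, 1.2)
        else:
            brightness[i] = geometry.other_brightness * rng.uniform(0.5, 1.5)
    return CellScene(labels=labels, classes=classes, marker_brightness=brightness)


def sample_level_params(preset: GroupPreset, sample_offset: float) -> tuple[float, float]:
    """Map a replicate's latent effect z to its (tau_m, a1) sample means.

    tau_m moves with +z, a1 with -z: lifetime up, free fraction down
    within a replicate, mirroring the free/bound shift.
    """
    taum = preset.taum_mean + sample_offset * preset.taum_sd
    a1 = preset.a1_mean - sample_offset * preset.a1_sd
    return float(taum), float(min(max(a1, 1e-3), 1 - 1e-3))


def draw_cell_params(
    preset: GroupPreset,
    sample_offset: float,
    n_cells: int,
    rng: np.random.Generator,
    tau1: float = DEFAULT_TAU1,
    tau2_bounds: tuple[float, float] = (800.0, 6000.0),
    max_redraws: int = 100,
) -> list[BiExpParams]:
    """Per-cell decay parameters around the replicate's sample means.

    Cell tau_m ~ Normal(sample tau_m, cell_cv * sample tau_m), cell a1
    ~ Normal(sample a1, cell_cv * sample a1) clipped to (0, 1); tau2
    follows from the tau_m identity at fixed tau1.  Draws whose tau2
    leaves ``tau2_bounds`` are redrawn (bounded, then an error).
    """
    taum_s, a1_s = sample_level_params(preset, sample_offset)
    out: list[BiExpParams] = []
    for _ in range(n_cells):
        for _ in range(max_redraws):
            taum_c = rng.normal(taum_s, preset.cell_cv * abs(taum_s))
            a1_c = float(np.clip(rng.normal(a1_s, preset.cell_cv * a1_s), 0.01, 0.99))
            if taum_c <= a1_c * tau1:
                continue
            tau2_c = solve_tau2(taum_c, a1_c, tau1)
            if tau2_bounds[0] <= tau2_c <= tau2_bounds[1]:
                out.append(BiExpParams(a1=a1_c, tau1=tau1, tau2=tau2_c))
                break
        else:
            raise DomainError(
                f"preset {preset.name!r}: could not draw a cell inside the "
                f"tau2 bounds after {max_redraws} attempts"
            )
    return out


def render_fov(
    scene: CellScene,
    grid: AcquisitionGrid,
    irf: IRFProfile,
    photons_per_pixel: float,
    rng: np.random.Generator | None = None,
    marker_noise_sd: float = 20.0,
    noise: bool = True,
) -> tuple[np.ndarray, MarkerImage]:
    """Render one FOV: Poisson decay stack + noisy marker image.

    Every pixel of a cell holds an independent Poisson realization of the
    cell's expected decay curve scaled to ``photons_per_pixel``;
    background pixels hold no signal (zero offset).  ``noise=False``
    returns the noise-free expectation (float stack, exact photon sums).
    """
    if scene.cell_params is None:
        raise DomainError("scene has no cell_params; call draw_cell_params first")
    if scene.labels.shape != (grid.height, grid.width):
        raise DomainError("scene does not match the acquisition grid")
    rng = rng if rng is not None else np.random.default_rng()
    if scene.cell_params:
        max_tau2 = max(p.tau2 for p in scene.cell_params)
        grid.check_window(max_tau2)
    T = grid.n_time_channels
    curves = np.array(
        [
            model_decay(replace(p, amplitude=float(photons_per_pixel)), irf, grid)
            for p in scene.cell_params
        ]
    )  # (n_cells, T)
    ys, xs = np.nonzero(scene.labels)
    cell_idx = scene.labels[ys, xs] - 1
    lam = curves[cell_idx]  # (n_cellpx, T)
    if noise:
        stack = np.zeros((T, grid.height, grid.width), dtype=np.uint16)
        draws = rng.poisson(lam).astype(np.uint16)
        stack[:, ys, xs] = draws.T
    else:
        stack = np.zeros((T, grid.height, grid.width), dtype=float)
        stack[:, ys, xs] = lam.T
    bright = np.zeros((grid.height, grid.width))
    bright[ys, xs] = scene.marker_brightness[cell_idx]
    marker = bright + rng.normal(0.0, marker_noise_sd, size=bright.shape)
    return stack, MarkerImage(intensity=np.clip(marker, 0.0, None))


def _spawned_rngs(design: ExperimentDesign):
    """Deterministic seed tree: child 0 drives replicate effects, then one
    child per (group, sample, fov) in design order."""
    n = len(design.groups) * design.n_samples * design.n_fovs
    children = np.random.SeedSequence(design.seed).spawn(1 + n)
    return np.random.default_rng(children[0]), children[1:]


def _replicate_effects(design: ExperimentDesign, rng: np.random.Generator) -> dict:
    """z_i per (group, sample); shared across groups when paired."""
    if design.paired:
        z = rng.standard_normal(design.n_samples)
        return {g: z for g in design.groups}
    return {g: rng.standard_normal(design.n_samples) for g in design.groups}


def iter_fovs(design: ExperimentDesign, irf: IRFProfile | None = None):
    """Generate every FOV of the design, one at a time.

    Yields dicts with the group label, sample/fov indices, the rendered
    stack and marker, the scene (with cell parameters attached) and the
    sample-level generative truth.  Fully reproducible from the design
    seed; FOVs are streamed so a whole experiment never sits in memory.
    """
    irf = irf or IRFProfile.gaussian(design.grid)
    eff_rng, fov_seeds = _spawned_rngs(design)
    z_by_group = _replicate_effects(design, eff_rng)
    n_mg, n_ot = design.cells_per_fov()
    # individual cell draws must respect the window guard (window > 4*tau2)
    tau2_hi = min(6000.0, design.grid.window / 4.0 * 0.999)
    k = 0
    for group, preset_name in design.groups.items():
        presets = PRESETS[preset_name]
        for s in range(design.n_samples):
            z = float(z_by_group[group][s])
            truth = {
                comp: sample_level_params(presets[comp], z)
                for comp in ("microglia", "non_microglia")
            }
            for f in range(design.n_fovs):
                rng = np.random.default_rng(fov_seeds[k])
                k += 1
                scene = make_scene(design.grid, n_mg, n_ot, design.geometry, rng)
                mg_params = draw_cell_params(
                    presets["microglia"], z, n_mg, rng,
                    tau2_bounds=(800.0, tau2_hi),
                )
                ot_params = draw_cell_params(
                    presets["non_microglia"], z, n_ot, rng,
                    tau2_bounds=(800.0, tau2_hi),
                )
                scene.cell_params = mg_params + ot_params
                stack, marker = render_fov(
                    scene,
                    design.grid,
                    irf,
                    design.photons_per_pixel,
                    rng,
                    marker_noise_sd=design.marker_noise_sd,
                )
                yield {
                    "group": group,
                    "preset": preset_name,
                    "sample": s,
                    "fov": f,
                    "z": z,
                    "sample_truth": truth,
                    "scene": scene,
                    "stack": stack,
                    "marker": marker,
                }


def simulate_experiment(
    design: ExperimentDesign,
    out_dir,
    irf: IRFProfile | None = None,
    overwrite: bool = False,
):
    """Write the full experiment to disk: stacks, markers, truth tables.

    Layout: ``<out>/<group>/sample_<s>/fov_<f>/{stack.tif, stack.json,
    marker.tif}`` plus ``cells.csv`` and ``samples.csv`` truth tables,
    the IRF, and a YAML echo of the design at the root.  Refuses an
    existing directory unless ``overwrite`` is set.
    """
    import shutil
    from pathlib import Path

    import pandas as pd
    import yaml

    from .io_cli import write_marker, write_stack

    out = Path(out_dir)
    if out.exists():
        if not overwrite:
            raise FileExistsError(
                f"{out} exists; pass overwrite=True to replace it"
            )
        shutil.rmtree(out)
    out.mkdir(parents=True)
    irf = irf or IRFProfile.gaussian(design.grid)
    irf.to_text(out / "irf.txt")
    design_echo = {
        "groups": dict(design.groups),
        "n_samples": design.n_samples,
        "n_fovs": design.n_fovs,
        "grid": {
            "n_time_channels": design.grid.n_time_channels,
            "channel_width": design.grid.channel_width,
            "height": design.grid.height,
            "width": design.grid.width,
        },
        "photons_per_pixel": design.photons_per_pixel,
        "paired": design.paired,
        "seed": design.seed,
    }
    (out / "design.yaml").write_text(yaml.safe_dump(design_echo, sort_keys=True))
    cell_rows = []
    sample_rows = {}
    for fov in iter_fovs(design, irf):
        fdir = out / fov["group"] / f"sample_{fov['sample']:02d}" / f"fov_{fov['fov']:02d}"
        fdir.mkdir(parents=True, exist_ok=True)
        write_stack(
            fov["stack"],
            design.grid,
            fdir / "stack.tif",
            seed=design.seed,
            extra={"group": fov["group"], "sample": fov["sample"], "fov": fov["fov"]},
        )
        write_marker(fov["marker"], fdir / "marker.tif")
        scene = fov["scene"]
        for i, params in enumerate(scene.cell_params):
            cell_rows.append(
                {
                    "group": fov["group"],
                    "sample": fov["sample"],
                    "fov": fov["fov"],
                    "cell_id": i + 1,
                    "cell_class": scene.classes[i],
                    "a1": params.a1,
                    "tau1": params.tau1,
                    "tau2": params.tau2,
                    "taum": params.taum,
                    "marker_brightness": scene.marker_brightness[i],
                }
            )
        for comp, (taum_s, a1_s) in fov["sample_truth"].items():
            sample_rows[(fov["group"], fov["sample"], comp)] = {
                "group": fov["group"],
                "sample": fov["sample"],
                "compartment": comp,
                "z": fov["z"],
                "taum_sample": taum_s,
                "a1_sample": a1_s,
            }
    pd.DataFrame(cell_rows).to_csv(out / "cells.csv", index=False)
    pd.DataFrame(sample_rows.values()).to_csv(out / "samples.csv", index=False)
    return out
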