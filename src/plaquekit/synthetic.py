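"""Ground-truthed synthetic scenes and expression matrices.

The imaging generator renders the kind of multi-channel fluorescence field
the quantification pipeline was written for: amyloid plaques as a bright
compact core plateau surrounded by a dimmer diffuse halo plateau (X04
channel), Lamp1 blobs of dystrophic axons near plaque rims, Iba1 microglia
as soma disks with thin processes, and small ApoE puncta — all at known
positions with analytic areas, plus additive Gaussian noise clipped at
zero.  The piecewise-constant core/halo profile is deliberate: it makes the
compact and diffuse truth areas exact (πr²) so percentile-mask recovery can
be checked analytically.

The expression generator emulates nRPKM matrices from sorted microglia of
two genotype groups with planted per-module log2 effects, Gaussian log-scale
noise, and dropout zeros.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genesets import GeneSet
from .grids import ImageGrid

__all__ = [
    "SceneSpec",
    "PlaqueTruth",
    "MicrogliaTruth",
    "SceneTruth",
    "make_scene",
    "ExprSpec",
    "ExpressionTruth",
    "make_expression",
]

CHANNELS = ("X04", "Iba1", "Lamp1", "ApoE")


@dataclass(frozen=True)
class SceneSpec:
    """Parameters of one synthetic fluorescence scene.

    Intensities are in arbitrary camera units with core > halo > background;
    ``noise_sd`` is the SD of additive Gaussian noise (clipped at zero), so
    the core signal-to-noise ratio is (core − background) / noise_sd.
    """

    width_um: float = 200.0
    height_um: float = 200.0
    pixel_size_um: float = 0.5
    n_plaques: int = 5
    core_radius_um: float = 8.0
    halo_radius_um: float = 14.0
    core_intensity: float = 200.0
    halo_intensity: float = 100.0
    background_intensity: float = 10.0
    noise_sd: float = 10.0
    channels: tuple[str, ...] = CHANNELS
    n_microglia: int = 10
    microglia_radius_um: float = 3.0
    lamp1_blobs_per_plaque: int = 4
    lamp1_blob_radius_um: float = 2.0
    lamp1_rim_offset_um: float = 3.0
    apoe_puncta_per_plaque: int = 6
    apoe_radius_um: float = 1.0
    min_center_distance_um: float | None = None  # default: cores disjoint, halos may touch
    seed: int = 0

    def __post_init__(self) -> None:
        if self.width_um <= 0 or self.height_um <= 0 or self.pixel_size_um <= 0:
            raise ValueError("scene dimensions and pixel size must be positive")
        if self.halo_radius_um < self.core_radius_um:
            raise ValueError("halo radius must be >= core radius")
        if not (self.core_intensity > self.halo_intensity > self.background_intensity >= 0):
            raise ValueError("need core > halo > background >= 0 intensities")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_plaques < 0:
            raise ValueError("n_plaques must be >= 0")
        unknown = set(self.channels) - set(CHANNELS)
        if unknown:
            raise ValueError(f"unknown channels: {sorted(unknown)}")

    @property
    def shape(self) -> tuple[int, int]:
        return (
            int(round(self.height_um / self.pixel_size_um)),
            int(round(self.width_um / self.pixel_size_um)),
        )


@dataclass(frozen=True)
class PlaqueTruth:
    center_row_um: float
    center_col_um: float
    core_radius_um: float
    halo_radius_um: float
    core_area_um2: float  # exact analytic pi r^2
    total_area_um2: float


@dataclass(frozen=True)
class MicrogliaTruth:
    center_row_um: float
    center_col_um: float
    radius_um: float


@dataclass
class SceneTruth:
    """Exact ground truth for one rendered scene."""

    plaques: list[PlaqueTruth] = field(default_factory=list)
    microglia: list[MicrogliaTruth] = field(default_factory=list)
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    pixel_size_um: float = 0.5

    def plaque_table(self) -> pd.DataFrame:
        cols = [
            "center_row_um",
            "center_col_um",
            "core_radius_um",
            "halo_radius_um",
            "core_area_um2",
            "total_area_um2",
        ]
        return pd.DataFrame([asdict(p) for p in self.plaques], columns=cols)


def _disk_mask(shape, center_rc_px, radius_px):
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center_rc_px[0]) ** 2 + (cc - center_rc_px[1]) ** 2 <= radius_px**2


def _place_centers(spec: SceneSpec, rng: np.random.Generator) -> list[tuple[float, float]]:
    """Rejection-sample plaque centers: cores disjoint, halos inside the frame."""
    margin = spec.halo_radius_um + spec.pixel_size_um
    if spec.n_plaques and (
        spec.width_um <= 2 * margin or spec.height_um <= 2 * margin
    ):
        raise ValueError("frame too small for the requested plaque radii")
    centers: list[tuple[float, float]] = []
    budget = 1000 * max(spec.n_plaques, 1)
    tries = 0
    min_sep = spec.min_center_distance_um
    if min_sep is None:
        min_sep = 2 * spec.core_radius_um + spec.pixel_size_um
    while len(centers) < spec.n_plaques:
        if tries >= budget:
            raise RuntimeError(
                f"could not place {spec.n_plaques} non-overlapping plaque cores in a "
                f"{spec.width_um}x{spec.height_um} um frame after {budget} tries; "
                "reduce plaque density or radii"
            )
        tries += 1
        r = rng.uniform(margin, spec.height_um - margin)
        c = rng.uniform(margin, spec.width_um - margin)
        if all((r - r0) ** 2 + (c - c0) ** 2 >= min_sep**2 for r0, c0 in centers):
            centers.append((r, c))
    return centers


def make_scene(spec: SceneSpec) -> tuple[dict[str, ImageGrid], SceneTruth]:
    """Render a multi-channel scene and its exact ground truth.

    Deterministic for a fixed spec (the seed lives in the spec).  Returns a
    dict of channel name → :class:`ImageGrid` plus a :class:`SceneTruth`
    with analytic per-plaque areas and rasterized true positive masks.
    """
    rng = np.random.default_rng(spec.seed)
    shape = spec.shape
    px = spec.pixel_size_um
    truth = SceneTruth(pixel_size_um=px)
    centers = _place_centers(spec, rng)

    core_mask = np.zeros(shape, dtype=bool)
    total_mask = np.zeros(shape, dtype=bool)
    for r_um, c_um in centers:
        center_px = (r_um / px, c_um / px)
        core = _disk_mask(shape, center_px, spec.core_radius_um / px)
        halo = _disk_mask(shape, center_px, spec.halo_radius_um / px)
        core_mask |= core
        total_mask |= halo
        truth.plaques.append(
            PlaqueTruth(
                center_row_um=r_um,
                center_col_um=c_um,
                core_radius_um=spec.core_radius_um,
                halo_radius_um=spec.halo_radius_um,
                core_area_um2=np.pi * spec.core_radius_um**2,
                total_area_um2=np.pi * spec.halo_radius_um**2,
            )
        )

    channels: dict[str, ImageGrid] = {}

    def _render(name: str, signal: np.ndarray) -> None:
        img = signal + spec.background_intensity
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, shape)
        channels[name] = ImageGrid(np.clip(img, 0.0, None), px, channel=name)

    if "X04" in spec.channels:
        x04 = np.zeros(shape)
        x04[total_mask] = spec.halo_intensity - spec.background_intensity
        x04[core_mask] = spec.core_intensity - spec.background_intensity
        truth.masks["X04"] = total_mask
        truth.masks["X04_core"] = core_mask
        _render("X04", x04)

    if "Lamp1" in spec.channels:
        lamp1_mask = np.zeros(shape, dtype=bool)
        for r_um, c_um in centers:
            for _ in range(spec.lamp1_blobs_per_plaque):
                theta = rng.uniform(0, 2 * np.pi)
                rad = spec.halo_radius_um + rng.uniform(0, spec.lamp1_rim_offset_um)
                br = np.clip(r_um + rad * np.sin(theta), 0, spec.height_um)
                bc = np.clip(c_um + rad * np.cos(theta), 0, spec.width_um)
                lamp1_mask |= _disk_mask(shape, (br / px, bc / px), spec.lamp1_blob_radius_um / px)
        truth.masks["Lamp1"] = lamp1_mask
        sig = np.zeros(shape)
        sig[lamp1_mask] = spec.core_intensity - spec.background_intensity
        _render("Lamp1", sig)

    if "Iba1" in spec.channels:
        iba1_mask = np.zeros(shape, dtype=bool)
        for _ in range(spec.n_microglia):
            r_um = rng.uniform(spec.microglia_radius_um, spec.height_um - spec.microglia_radius_um)
            c_um = rng.uniform(spec.microglia_radius_um, spec.width_um - spec.microglia_radius_um)
            soma = _disk_mask(shape, (r_um / px, c_um / px), spec.microglia_radius_um / px)
            iba1_mask |= soma
            truth.microglia.append(MicrogliaTruth(r_um, c_um, spec.microglia_radius_um))
            # thin processes: 1-px lines radiating from the soma
            for _ in range(3):
                theta = rng.uniform(0, 2 * np.pi)
                length_um = rng.uniform(5.0, 12.0)
                n_steps = max(int(length_um / px), 1)
                t = np.linspace(0, length_um, n_steps)
                rr = np.clip(((r_um + t * np.sin(theta)) / px).astype(int), 0, shape[0] - 1)
                cc = np.clip(((c_um + t * np.cos(theta)) / px).astype(int), 0, shape[1] - 1)
                iba1_mask[rr, cc] = True
        truth.masks["Iba1"] = iba1_mask
        sig = np.zeros(shape)
        sig[iba1_mask] = spec.core_intensity - spec.background_intensity
        _render("Iba1", sig)

    if "ApoE" in spec.channels:
        apoe_mask = np.zeros(shape, dtype=bool)
        for r_um, c_um in centers:
            for _ in range(spec.apoe_puncta_per_plaque):
                theta = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0, spec.halo_radius_um)
                pr = r_um + rad * np.sin(theta)
                pc = c_um + rad * np.cos(theta)
                apoe_mask |= _disk_mask(shape, (pr / px, pc / px), spec.apoe_radius_um / px)
        truth.masks["ApoE"] = apoe_mask
        sig = np.zeros(shape)
        sig[apoe_mask] = spec.core_intensity - spec.background_intensity
        _render("ApoE", sig)

    return channels, truth


@dataclass(frozen=True)
class ExprSpec:
    """Parameters of one synthetic nRPKM expression matrix.

    ``modules`` maps module name → tuple of member gene ids (drawn from the
    g0..g{n_genes-1} universe); ``effects`` maps module name → planted log2
    effect added to group B.  ``dropout`` is the probability that a value is
    replaced by exactly 0 after exponentiation.
    """

    n_genes: int = 500
    n_samples_per_group: int = 7
    modules: dict[str, tuple[str, ...]] = field(default_factory=dict)
    effects: dict[str, float] = field(default_factory=dict)
    baseline_log2_mean: float = 5.0
    baseline_log2_sd: float = 2.0
    noise_sd: float = 0.5
    dropout: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes < 1 or self.n_samples_per_group < 1:
            raise ValueError("n_genes and n_samples_per_group must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        universe = {f"g{i}" for i in range(self.n_genes)}
        for name, genes in self.modules.items():
            unknown = set(genes) - universe
            if unknown:
                raise ValueError(
                    f"module {name!r} references unknown genes: {sorted(unknown)[:5]}"
                )

    def gene_ids(self) -> list[str]:
        return [f"g{i}" for i in range(self.n_genes)]

    def gene_sets(self) -> list[GeneSet]:
        return [GeneSet(name, genes) for name, genes in self.modules.items()]


@dataclass(frozen=True)
class ExpressionTruth:
    """Planted per-module log2 effects and the group assignment."""

    effects: dict[str, float]
    groups: dict[str, str]

    def to_json(self) -> str:
        return json.dumps({"effects": self.effects, "groups": self.groups}, indent=2)


def make_expression(spec: ExprSpec) -> tuple[pd.DataFrame, pd.Series, ExpressionTruth]:
    """Simulate a genes × samples nRPKM matrix with planted module effects.

    Log2 values are baseline + per-gene offset + group effect (module genes,
    group B only) + Gaussian noise; nRPKM = 2^log2 with dropout zeros applied
    independently afterwards.  Returns the matrix, a sample → group series
    and the truth record.
    """
    rng = np.random.default_rng(spec.seed)
    genes = spec.gene_ids()
    n = spec.n_samples_per_group
    samples = [f"A{i + 1}" for i in range(n)] + [f"B{i + 1}" for i in range(n)]
    groups = pd.Series(["A"] * n + ["B"] * n, index=pd.Index(samples, name="sample"))

    base = spec.baseline_log2_mean + rng.normal(0.0, spec.baseline_log2_sd, len(genes))
    log2 = base[:, None] + rng.normal(0.0, spec.noise_sd, (len(genes), 2 * n))
    gene_index = {g: i for i, g in enumerate(genes)}
    for name, members in spec.modules.items():
        eff = spec.effects.get(name, 0.0)
        rows = [gene_index[g] for g in members]
        log2[np.ix_(rows, range(n, 2 * n))] += eff

    nrpkm = np.power(2.0, log2)
    if spec.dropout > 0:
        nrpkm[rng.random(nrpkm.shape) < spec.dropout] = 0.0
    matrix = pd.DataFrame(nrpkm, index=pd.Index(genes, name="gene"), columns=samples)
    truth = ExpressionTruth(
        effects={k: spec.effects.get(k, 0.0) for k in spec.modules},
        groups=groups.to_dict(),
    )
    return matrix, groups, truth
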