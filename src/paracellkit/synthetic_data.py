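"""Synthetic inputs with known ground truth for every pipeline stage.

The generators here are the test bed for the whole package: epithelial
mosaic images whose junctional intensities depend on the genotype pair of
the adjacent cells, Transwell electrophysiology records drawn around true
ionic permeabilities, single-timepoint tracer assays, and reference ORFs
with engineered knockout alleles.

Design principles:

* every generator is a pure function of its seed — identical spec and
  seed give byte-identical output;
* the ground truth is pushed through the *same* forward models the
  analysis modules use (GHK potential, Kimizuka-Koketsu conductance,
  ribbon-density rendering), so round-trip tests exercise true inverses
  rather than parallel re-implementations.

The mosaic generator emulates a quasi-uniform MDCK-like monolayer:
blue-noise cell centres, Voronoi tessellation, junctional ribbons drawn
on the shared cell edges, Gaussian PSF blur and additive read noise.
Boundary-class junction intensity interpolates between the knockout
background and the control level:  mean_B = mean_KO + f * (mean_CTL -
mean_KO), with f the "boundary fraction" recovered downstream by the
(D_Boundary - D_KO)/(D_CTL - D_KO) statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as _dc_field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import Voronoi, cKDTree

from . import barrier_assays as ba
from .constants import FARADAY, MM_TO_MOL_PER_CM3, R_GAS, T_BODY_K
from .errors import OutOfRangeError
from .junction_quant import GenotypeField, MonolayerImage

__all__ = [
    "MosaicSpec",
    "EphysTruth",
    "IndelSpec",
    "simulate_monolayer",
    "simulate_ephys",
    "simulate_tracer",
    "simulate_orf_and_alleles",
]


# ---------------------------------------------------------------------------
# mosaic monolayer images
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MosaicSpec:
    """Parameters of one synthetic mosaic monolayer image.

    Intensities are arbitrary fluorescence units.  ``ctl_intensity`` /
    ``ko_intensity`` are the per-edge target-channel line amplitudes for
    junctions between two control / two knockout cells;
    ``boundary_fraction_f`` places control-knockout boundary edges on the
    line between those two levels.  ``edge_cv`` is the per-edge
    multiplicative intensity CV (biological edge-to-edge variability).
    """

    n_cells: int = 200
    field_um: float = 100.0
    pixel_size_um: float = 0.1
    ko_fraction: float = 0.5
    ctl_intensity: float = 1000.0
    ko_intensity: float = 150.0
    boundary_fraction_f: float = 0.45
    edge_cv: float = 0.10
    marker_intensity: float = 1000.0
    psf_sigma_um: float = 0.2
    noise_sd: float = 2.0
    reporter_on: bool = False
    reporter_intensity: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cells < 4:
            raise OutOfRangeError("n_cells must be >= 4")
        if not 0.0 <= self.ko_fraction <= 1.0:
            raise OutOfRangeError("ko_fraction must lie in [0, 1]")
        if min(self.ctl_intensity, self.ko_intensity) < 0:
            raise OutOfRangeError("junction intensities must be >= 0")
        if 0.0 <= self.boundary_fraction_f <= 1.0:
            b = self.boundary_intensity
            if not self.ko_intensity <= b <= self.ctl_intensity:
                raise OutOfRangeError("boundary intensity must lie between KO and CTL levels")

    @property
    def boundary_intensity(self) -> float:
        return self.ko_intensity + self.boundary_fraction_f * (
            self.ctl_intensity - self.ko_intensity
        )

    def class_intensity(self, boundary_class: str) -> float:
        return {
            "CTL_CTL": self.ctl_intensity,
            "KO_KO": self.ko_intensity,
            "BOUNDARY": self.boundary_intensity,
        }[boundary_class]


def _blue_noise_centers(rng: np.random.Generator, n: int, field: float) -> np.ndarray:
    """Minimum-distance rejection sampling of cell centres (x, y in um)."""
    dmin = 0.6 * math.sqrt(field**2 / n)
    pts: list[np.ndarray] = []
    attempts = 0
    while len(pts) < n:
        cand = rng.uniform(0.0, field, size=2)
        attempts += 1
        if attempts > 50000:
            dmin *= 0.9  # relax spacing rather than loop forever on dense packings
            attempts = 0
        if all(np.hypot(*(cand - p)) >= dmin for p in pts):
            pts.append(cand)
    return np.asarray(pts)


def _clip_segment_to_box(
    p0: np.ndarray, p1: np.ndarray, lo: float, hi: float
) -> Optional[tuple[np.ndarray, np.ndarray]]:
    """Liang-Barsky clip of a segment to the square [lo, hi]^2."""
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for axis in (0, 1):
        for sign, bound in ((-1.0, lo), (1.0, hi)):
            denom = sign * d[axis]
            num = sign * (bound - p0[axis])
            if denom == 0:
                if num < 0:
                    return None
                continue
            t = num / denom
            if denom < 0:
                t0 = max(t0, t)
            else:
                t1 = min(t1, t)
            if t0 > t1:
                return None
    return p0 + t0 * d, p0 + t1 * d


def _voronoi_edges(centers: np.ndarray, field: float) -> list[tuple[int, int, np.ndarray, np.ndarray]]:
    """Finite Voronoi ridge segments clipped to the field.

    Returns (cell_a, cell_b, endpoint0_um, endpoint1_um) per shared edge;
    unbounded ridges are extended far beyond the field before clipping.
    """
    vor = Voronoi(centers)
    center_mean = centers.mean(axis=0)
    edges = []
    for (a, b), verts in zip(vor.ridge_points, vor.ridge_vertices):
        v0, v1 = verts
        if v0 == -1 and v1 == -1:
            continue
        if v0 == -1 or v1 == -1:
            finite = vor.vertices[v1 if v0 == -1 else v0]
            t = centers[b] - centers[a]
            t = t / np.linalg.norm(t)
            normal = np.array([-t[1], t[0]])
            midpoint = 0.5 * (centers[a] + centers[b])
            if np.dot(midpoint - center_mean, normal) < 0:
                normal = -normal
            far = finite + normal * 4.0 * field
            seg = _clip_segment_to_box(finite, far, 0.0, field)
        else:
            seg = _clip_segment_to_box(vor.vertices[v0], vor.vertices[v1], 0.0, field)
        if seg is None:
            continue
        e0, e1 = seg
        if np.linalg.norm(e1 - e0) < 0.3:  # sliver edges below rendering resolution
            continue
        edges.append((int(a), int(b), e0, e1))
    return edges


def _draw_edge(canvas: np.ndarray, e0_px: np.ndarray, e1_px: np.ndarray, value: float) -> None:
    """Deposit ``value`` per pixel of path length along the segment.

    Line-integral rendering (dense sub-pixel sampling, deposit weighted by
    arc length) keeps the deposited mass per unit length independent of
    segment orientation, which a plain rasterised line does not.
    """
    length = float(np.linalg.norm(e1_px - e0_px))
    n = max(2, int(math.ceil(length / 0.25)) + 1)
    ts = np.linspace(0.0, 1.0, n)
    pts = e0_px[None, :] + ts[:, None] * (e1_px - e0_px)[None, :]
    step = length / (n - 1)
    rows = np.clip(np.round(pts[:, 1]).astype(int), 0, canvas.shape[0] - 1)
    cols = np.clip(np.round(pts[:, 0]).astype(int), 0, canvas.shape[1] - 1)
    np.add.at(canvas, (rows, cols), value * step)


def simulate_monolayer(
    spec: MosaicSpec,
) -> tuple[MonolayerImage, GenotypeField, pd.DataFrame]:
    """Render one mosaic monolayer.

    Returns the multichannel image (marker, target, and optionally a
    knockout reporter channel), the ground-truth genotype label field, and
    a per-edge truth table (cells, genotypes, boundary class, drawn
    amplitude, length).
    """
    rng = np.random.default_rng(spec.seed)
    field = spec.field_um
    px = spec.pixel_size_um
    npx = int(round(field / px))

    centers = _blue_noise_centers(rng, spec.n_cells, field)
    genotypes = (rng.random(spec.n_cells) < spec.ko_fraction).astype(np.int32)

    if spec.ko_fraction in (0.0, 1.0):
        import warnings

        warnings.warn("ko_fraction is 0 or 1: the mosaic contains no boundary edges", stacklevel=2)

    edges = _voronoi_edges(centers, field)

    # genotype label image: nearest-centre assignment on the pixel grid
    grid_r, grid_c = np.mgrid[0:npx, 0:npx]
    pix_xy = np.column_stack([(grid_c.ravel() + 0.5) * px, (grid_r.ravel() + 0.5) * px])
    _, owner = cKDTree(centers).query(pix_xy)
    labels = genotypes[owner].reshape(npx, npx)

    marker_amp = np.zeros((npx, npx), dtype=float)
    target_amp = np.zeros((npx, npx), dtype=float)
    rows = []
    for edge_id, (a, b, e0, e1) in enumerate(edges):
        ga, gb = int(genotypes[a]), int(genotypes[b])
        if ga == gb == 0:
            cls = "CTL_CTL"
        elif ga == gb == 1:
            cls = "KO_KO"
        else:
            cls = "BOUNDARY"
        amp = max(0.0, spec.class_intensity(cls) * (1.0 + spec.edge_cv * rng.standard_normal()))
        e0_px, e1_px = e0 / px, e1 / px
        _draw_edge(marker_amp, e0_px, e1_px, spec.marker_intensity)
        _draw_edge(target_amp, e0_px, e1_px, amp)
        rows.append(
            {
                "edge_id": edge_id,
                "cell_a": a,
                "cell_b": b,
                "genotype_a": ga,
                "genotype_b": gb,
                "boundary_class": cls,
                "amplitude": amp,
                "length_um": float(np.linalg.norm(e1 - e0)),
                "x0_um": float(e0[0]),
                "y0_um": float(e0[1]),
                "x1_um": float(e1[0]),
                "y1_um": float(e1[1]),
            }
        )
    truth = pd.DataFrame(rows)

    sigma_px = spec.psf_sigma_um / px
    channels: dict[str, np.ndarray] = {}
    for name, amp_img in (("marker", marker_amp), ("target", target_amp)):
        img = ndimage.gaussian_filter(amp_img, sigma_px) if sigma_px > 0 else amp_img.copy()
        if spec.noise_sd > 0:
            img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
        channels[name] = np.clip(img, 0.0, None)

    roles = {"tj_marker": "marker", "target": "target"}
    if spec.reporter_on:
        rep = (labels == 1).astype(float) * spec.reporter_intensity
        rep = ndimage.gaussian_filter(rep, sigma_px) if sigma_px > 0 else rep
        if spec.noise_sd > 0:
            rep = rep + rng.normal(0.0, spec.noise_sd, size=rep.shape)
        channels["reporter"] = np.clip(rep, 0.0, None)
        roles["genotype_reporter"] = "reporter"

    image = MonolayerImage(channels=channels, pixel_size_um=px, channel_roles=roles)
    return image, GenotypeField(labels=labels, provenance="ground_truth"), truth


# ---------------------------------------------------------------------------
# electrophysiology records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EphysTruth:
    """Ground-truth permeabilities and noise levels for one condition."""

    condition: str
    true_p_na: float  # cm/s
    true_p_cl: float  # cm/s
    n_filters: int = 5
    conductance_cv: float = 0.05
    potential_noise_mV: float = 0.3
    daily_multiplier: Sequence[float] = (1.0,)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.true_p_na, self.true_p_cl) <= 0:
            raise OutOfRangeError("true permeabilities must be positive")
        if any(m <= 0 for m in self.daily_multiplier):
            raise OutOfRangeError("daily multipliers must be positive")
        if self.n_filters < 1:
            raise OutOfRangeError("n_filters must be >= 1")


def simulate_ephys(
    truth: EphysTruth,
    apical: Optional[ba.IonicSolution] = None,
    basolateral: Optional[ba.IonicSolution] = None,
    temperature_K: float = T_BODY_K,
    blank_resistance_ohm: float = 120.0,
    filter_area_cm2: float = ba.DEFAULT_FILTER_AREA_CM2,
) -> list[ba.EphysMeasurement]:
    """Draw noisy Transwell records around the true permeabilities.

    The true TER and dilution potential are computed through the package's
    own forward models (Kimizuka-Koketsu conductance and GHK potential at
    the apical bath concentration).  Per filter and day, the conductance
    receives a lognormal multiplicative factor (median 1, log-sd
    ``conductance_cv``) times the day multiplier, and the potential a
    Gaussian offset of sd ``potential_noise_mV``.
    """
    apical = apical or ba.IonicSolution.solution_a()
    basolateral = basolateral or ba.IonicSolution.solution_b()
    rng = np.random.default_rng(truth.seed)

    eta = truth.true_p_na / truth.true_p_cl
    v_true = ba.ghk_dilution_potential(eta, apical, basolateral, temperature_K)
    c = apical.na_mM * MM_TO_MOL_PER_CM3
    g_true = (FARADAY**2 / (R_GAS * temperature_K)) * c * (truth.true_p_na + truth.true_p_cl)

    records: list[ba.EphysMeasurement] = []
    for day_idx, mult in enumerate(truth.daily_multiplier, start=1):
        for i in range(truth.n_filters):
            g = g_true * mult
            if truth.conductance_cv > 0:
                g *= math.exp(rng.normal(0.0, truth.conductance_cv))
            ter = 1.0 / g
            v = v_true
            if truth.potential_noise_mV > 0:
                v += rng.normal(0.0, truth.potential_noise_mV)
            records.append(
                ba.EphysMeasurement(
                    raw_resistance_ohm=blank_resistance_ohm + ter / filter_area_cm2,
                    blank_resistance_ohm=blank_resistance_ohm,
                    filter_area_cm2=filter_area_cm2,
                    dilution_potential_mV=v,
                    apical=apical,
                    basolateral=basolateral,
                    condition=truth.condition,
                    day=day_idx,
                    replicate_id=f"{truth.condition}-d{day_idx}-r{i + 1}",
                    temperature_K=temperature_K,
                )
            )
    return records


# ---------------------------------------------------------------------------
# tracer assays
# ---------------------------------------------------------------------------

def simulate_tracer(
    true_p_cm_s: float,
    seed: int = 0,
    area_cm2: float = ba.DEFAULT_FILTER_AREA_CM2,
    c0_mol_per_cm3: float = 2e-7,  # 0.2 mM basolateral tracer
    duration_s: float = 3600.0,
    apical_volume_cm3: float = 0.5,
    curve_slope: float = 1e12,  # fluorescence units per (mol/cm^3)
    curve_intercept: float = 20.0,
    noise_sd: float = 0.0,
    n_standards: int = 6,
    tracer: str = "fluorescein",
) -> ba.TracerAssay:
    """Forward-simulate one single-timepoint flux assay.

    Accumulated tracer Q = P * A * C0 * t; the apical concentration maps to
    fluorescence through an affine ground-truth curve, from which the
    standard-curve points are generated as well (plus optional Gaussian
    read noise on every fluorescence value).
    """
    if true_p_cm_s < 0:
        raise OutOfRangeError("true permeability must be >= 0")
    rng = np.random.default_rng(seed)
    q_mol = true_p_cm_s * area_cm2 * c0_mol_per_cm3 * duration_s
    conc_apical = q_mol / apical_volume_cm3

    cmax = max(2.0 * conc_apical, 1e-10)
    std_conc = np.linspace(0.0, cmax, n_standards)
    std_fluor = curve_intercept + curve_slope * std_conc
    sample_fluor = curve_intercept + curve_slope * conc_apical
    if noise_sd > 0:
        std_fluor = std_fluor + rng.normal(0.0, noise_sd, size=std_fluor.shape)
        sample_fluor += rng.normal(0.0, noise_sd)

    return ba.TracerAssay(
        standard_curve=tuple(zip(std_conc.tolist(), std_fluor.tolist())),
        sample_fluorescence=float(sample_fluor),
        apical_volume_cm3=apical_volume_cm3,
        duration_s=duration_s,
        area_cm2=area_cm2,
        c0=c0_mol_per_cm3,
        tracer=tracer,
    )


# ---------------------------------------------------------------------------
# reference ORFs and knockout alleles
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndelSpec:
    """One engineered mutation: ``kind`` in {'del', 'ins', 'sub'},
    ``pos_nt`` a 0-based reference nucleotide offset."""

    allele_id: str
    kind: str
    pos_nt: int
    length: int = 0
    seq: str = ""

    def __post_init__(self) -> None:
        if self.kind not in ("del", "ins", "sub"):
            raise OutOfRangeError(f"unknown indel kind {self.kind!r}")
        if self.kind == "del" and self.length < 1:
            raise OutOfRangeError("deletion needs length >= 1")
        if self.kind in ("ins", "sub") and not self.seq:
            raise OutOfRangeError(f"{self.kind} needs a sequence")


_SAFE_CODONS = sorted(
    {
        a + b + c
        for a in "ACGT"
        for b in "ACGT"
        for c in "ACGT"
    }
    - {"TAA", "TAG", "TGA", "ATG"}
)


def _expected_category(ref_seq: str, spec: IndelSpec) -> str:
    if spec.kind == "del":
        if spec.pos_nt < 3 and spec.pos_nt + spec.length > 0:
            # the deletion touches the start codon, but the junction can
            # recreate an ATG; judge the reconstructed allele directly
            mutant = ref_seq[: spec.pos_nt] + ref_seq[spec.pos_nt + spec.length :]
            if mutant[:3] != "ATG":
                return "START_LOST"
        return "FRAMESHIFT" if spec.length % 3 != 0 else "IN_FRAME"
    if spec.kind == "ins":
        return "FRAMESHIFT" if len(spec.seq) % 3 != 0 else "IN_FRAME"
    # substitution
    changed = any(
        ref_seq[spec.pos_nt + i] != b for i, b in enumerate(spec.seq)
    )
    if not changed:
        return "WILD_TYPE"
    if any(spec.pos_nt + i < 3 and ref_seq[spec.pos_nt + i] != b for i, b in enumerate(spec.seq)):
        return "START_LOST"
    return "IN_FRAME"


def simulate_orf_and_alleles(
    n_codons: int = 30,
    alt_start_codon: int = 24,
    indel_specs: Optional[Sequence[IndelSpec]] = None,
    seed: int = 0,
):
    """Random reference ORF with a planted downstream in-frame ATG, plus
    mutant alleles and their expected classifications.

    The ORF begins with ATG, carries its only other frame-0 ATG at codon
    ``alt_start_codon``, has no internal stop, and ends with a TAA stop
    codon.  ``indel_specs`` defaults to a small panel covering the
    canonical outcomes (start-loss, +/-1 frameshift, in-frame deletion,
    a large 52-nt deletion, and a silent-length substitution).

    Returns ``(ReferenceORF, alleles dict, truth DataFrame)``.
    """
    from .genotyping import ReferenceORF  # local import to avoid cycle at module load

    if not 2 <= alt_start_codon <= n_codons - 1:
        raise OutOfRangeError("need 2 <= alt_start_codon <= n_codons - 1")
    rng = np.random.default_rng(seed)
    codons = ["ATG"]
    for k in range(2, n_codons):
        codons.append(_SAFE_CODONS[rng.integers(0, len(_SAFE_CODONS))])
    codons.append("TAA")
    codons[alt_start_codon - 1] = "ATG"
    ref_seq = "".join(codons)
    reference = ReferenceORF(nucleotide_sequence=ref_seq, id=f"synthetic_orf_{seed}")

    if indel_specs is None:
        indel_specs = [
            IndelSpec("wt", "sub", 6, seq=ref_seq[6:9]),  # no change at all
            IndelSpec("del1", "del", 7, length=1),
            IndelSpec("ins1", "ins", 8, seq="A"),
            IndelSpec("del3", "del", 6, length=3),
            IndelSpec("start_del", "del", 0, length=4),
        ]
        if len(ref_seq) >= 150:  # large deletions only on ORFs long enough to stay alignable
            indel_specs = list(indel_specs) + [IndelSpec("del52", "del", 2, length=52)]

    alleles: dict[str, str] = {}
    rows = []
    for spec in indel_specs:
        if spec.kind == "del":
            if spec.pos_nt < 0 or spec.pos_nt + spec.length > len(ref_seq):
                raise OutOfRangeError(f"deletion {spec.allele_id!r} outside the sequence")
            seq = ref_seq[: spec.pos_nt] + ref_seq[spec.pos_nt + spec.length :]
            net = -spec.length
        elif spec.kind == "ins":
            if not 0 <= spec.pos_nt <= len(ref_seq):
                raise OutOfRangeError(f"insertion {spec.allele_id!r} outside the sequence")
            seq = ref_seq[: spec.pos_nt] + spec.seq + ref_seq[spec.pos_nt :]
            net = len(spec.seq)
        else:
            if spec.pos_nt < 0 or spec.pos_nt + len(spec.seq) > len(ref_seq):
                raise OutOfRangeError(f"substitution {spec.allele_id!r} outside the sequence")
            seq = (
                ref_seq[: spec.pos_nt]
                + spec.seq
                + ref_seq[spec.pos_nt + len(spec.seq) :]
            )
            net = 0
        alleles[spec.allele_id] = seq
        rows.append(
            {
                "allele_id": spec.allele_id,
                "kind": spec.kind,
                "pos_nt": spec.pos_nt,
                "net_indel_nt": net if _expected_category(ref_seq, spec) != "WILD_TYPE" or net else 0,
                "expected_category": _expected_category(ref_seq, spec),
            }
        )
    return reference, alleles, pd.DataFrame(rows)
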