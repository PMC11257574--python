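"""Synthetic inputs with known ground truth for every pipeline stage.

Four generator families emulate the input classes the pipeline consumes:

* two-chain "predicted" models with planted inter-chain contacts at chosen
  distances and assigned per-residue confidence;
* assembled multi-chain complexes with residues that are exposed (placed on
  a convex exterior) or buried (caged by neighbouring atoms) by
  construction;
* division-plane image stacks with ring vs disk signal geometry, optional
  PSF blur, Poisson noise and a planted second-channel axial offset;
* FRAP traces following m1 + m2*exp(-m3*t) with acquisition photobleaching
  drift, background and noise.

Structures are poly-alanine-like residue clusters on rigid, non-clashing
scaffolds: simple enough that planted geometry is exact, rich enough
(multi-atom residues) to exercise heavy-atom minimum distances and SASA.
Every generator is deterministic for a fixed seed and serialises its ground
truth as JSON next to the fixture it writes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .accessibility import compute_sasa, relative_sasa, sphere_points
from .fluor_quant import ImageStack
from .frap import FRAPTrace
from .model_io import Atom, Chain, Residue, StructureModel

__all__ = [
    "PairGroundTruth",
    "ComplexGroundTruth",
    "StackGroundTruth",
    "FrapGroundTruth",
    "make_pair_model",
    "make_complex_model",
    "make_division_stack",
    "make_frap_trace",
    "division_pattern_mask",
]

# rigid local residue geometry (A): a compact 5-atom alanine-like cluster.
# All atoms except CB lie in the local y=0 plane within 1.0 A of the centre;
# CB sticks out 0.9 A along +/-y, so the minimum heavy-atom distance between
# two residues facing each other along y is exactly their CB-CB distance.
_BASE_ATOMS = [
    ("N", "N", (-0.70, 0.0, 0.45)),
    ("CA", "C", (0.00, 0.0, 0.00)),
    ("C", "C", (0.70, 0.0, 0.45)),
    ("O", "O", (0.90, 0.0, -0.45)),
]
_CB_OUT = 0.9
_RES_SPACING = 8.0  # A between residue centres along a chain
_CHAIN_GAP = 10.0  # A between non-contacting chains (min atom distance 8.2)
_GUARD = 6.0  # non-planted inter-chain residue pairs stay beyond this


def _write_json(obj, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True)


def _cluster(center: np.ndarray, cb_sign: float, name_suffix: str = "") -> list[Atom]:
    atoms = [
        Atom(name=n, element=el, x=center[0] + dx, y=center[1] + dy, z=center[2] + dz)
        for n, el, (dx, dy, dz) in _BASE_ATOMS
    ]
    atoms.append(
        Atom(name="CB", element="C", x=center[0], y=center[1] + cb_sign * _CB_OUT, z=center[2])
    )
    return atoms


# --------------------------------------------------------------------------
# pairwise models with planted contacts

@dataclass
class PairGroundTruth:
    """Planted contacts and confidence labels of one two-chain model."""

    planted_contacts: list[dict]  # {res_a, res_b, distance}
    plddt_a: list[float]
    plddt_b: list[float]
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        _write_json(dataclasses.asdict(self), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "PairGroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))


def _per_residue(values, n: int, what: str) -> list[float]:
    if np.isscalar(values):
        return [float(values)] * n
    values = [float(v) for v in values]
    if len(values) != n:
        raise ValueError(f"{what}: expected {n} values, got {len(values)}")
    return values


def make_pair_model(
    n_res_a: int,
    n_res_b: int,
    n_planted_contacts: int,
    contact_distance_range: tuple[float, float] = (3.0, 4.0),
    plddt_a: float | Sequence[float] = 90.0,
    plddt_b: float | Sequence[float] = 90.0,
    seed: int = 0,
    model_id: str = "pair",
    seq_start_a: int = 1,
    seq_start_b: int = 1,
    chain_ids: tuple[str, str] = ("A", "B"),
) -> tuple[StructureModel, PairGroundTruth]:
    """Two-chain model with exactly ``n_planted_contacts`` planted contacts.

    The planted residue pairs have a minimum heavy-atom distance drawn
    uniformly from ``contact_distance_range`` (a subset of (2.5, 4.0]);
    every other inter-chain residue pair sits beyond 6 A by construction.
    """
    lo, hi = contact_distance_range
    if not (2.5 < lo <= hi <= 4.0):
        raise ValueError("contact_distance_range must lie within (2.5, 4.0]")
    n_pairable = min(n_res_a, n_res_b)
    if not 0 <= n_planted_contacts <= n_pairable:
        raise ValueError(
            f"cannot plant {n_planted_contacts} contacts with chains of "
            f"{n_res_a} and {n_res_b} residues"
        )
    rng = np.random.default_rng(seed)
    planted_idx = np.sort(rng.choice(n_pairable, size=n_planted_contacts, replace=False))
    distances = rng.uniform(lo, hi, size=n_planted_contacts)
    target = dict(zip((int(i) for i in planted_idx), (float(d) for d in distances)))

    vals_a = _per_residue(plddt_a, n_res_a, "plddt_a")
    vals_b = _per_residue(plddt_b, n_res_b, "plddt_b")

    residues_a = []
    for i in range(n_res_a):
        center = np.array([i * _RES_SPACING, 0.0, 0.0])
        residues_a.append(
            Residue(
                seq_index=seq_start_a + i,
                name="ALA",
                atoms=_cluster(center, cb_sign=+1.0),
                plddt=vals_a[i],
            )
        )
    residues_b = []
    for j in range(n_res_b):
        # planted partners drop down over their chain-A counterpart so that
        # their CB-CB distance equals the requested contact distance
        y = target[j] + 2 * _CB_OUT if j in target else _CHAIN_GAP
        center = np.array([j * _RES_SPACING, y, 0.0])
        residues_b.append(
            Residue(
                seq_index=seq_start_b + j,
                name="ALA",
                atoms=_cluster(center, cb_sign=-1.0),
                plddt=vals_b[j],
            )
        )
    model = StructureModel(
        model_id=model_id,
        chains=[
            Chain(chain_id=chain_ids[0], residues=residues_a),
            Chain(chain_id=chain_ids[1], residues=residues_b),
        ],
    )
    truth = PairGroundTruth(
        planted_contacts=[
            {
                "res_a": seq_start_a + i,
                "res_b": seq_start_b + i,
                "distance": target[i],
            }
            for i in sorted(target)
        ],
        plddt_a=vals_a,
        plddt_b=vals_b,
        seed=seed,
        params={
            "n_res_a": n_res_a,
            "n_res_b": n_res_b,
            "contact_distance_range": [lo, hi],
        },
    )
    return model, truth


# --------------------------------------------------------------------------
# assembled complexes with labelled exposed / buried residues

@dataclass
class ComplexGroundTruth:
    """Exposure labels of every content residue of a synthetic complex."""

    labels: dict  # chain_id -> {seq_index(str): "exposed"|"buried"}
    buried_fraction: float
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        _write_json(dataclasses.asdict(self), path)

    @classmethod
    def from_json(cls, path: str | Path) -> "ComplexGroundTruth":
        with open(path) as fh:
            return cls(**json.load(fh))

    def interface_residues(self) -> list[tuple[str, int, str]]:
        """All labelled residues as (subunit, seq_index, name) triples."""
        return [
            (chain, int(seq), "ALA")
            for chain, per in sorted(self.labels.items())
            for seq in sorted(per, key=int)
        ]

    def expected_percent_accessible(self) -> float:
        labels = [v for per in self.labels.values() for v in per.values()]
        return 100.0 * sum(v == "exposed" for v in labels) / len(labels)


_CAGE_CHAIN = "X"
_CAGE_RADIUS = 3.0  # A; 16 cage atoms at this radius fully occlude a CA atom
_CAGE_POINTS = 16


def make_complex_model(
    n_chains: int = 4,
    residues_per_chain: int = 10,
    buried_fraction: float = 0.3,
    seed: int = 0,
    model_id: str = "complex",
    validate: bool = True,
) -> tuple[StructureModel, ComplexGroundTruth]:
    """Multi-chain complex with construction-labelled exposure.

    Exposed residues are 5-atom clusters spaced widely on a convex ring;
    buried residues are single CA atoms caged inside a shell of carbon
    atoms (carried by an extra cage chain 'X').  With ``validate=True`` the
    construction is self-checked by an actual SASA computation (buried
    relative SASA < 0.05, exposed > 0.5).
    """
    if not 0.0 <= buried_fraction <= 1.0:
        raise ValueError("buried_fraction must be in [0, 1]")
    if n_chains < 1 or n_chains > 20:
        raise ValueError("n_chains must be in 1..20")
    rng = np.random.default_rng(seed)
    chain_ids = [chr(ord("A") + i) for i in range(n_chains)]

    total = n_chains * residues_per_chain
    n_buried = int(round(buried_fraction * total))
    flat = [(cid, s) for cid in chain_ids for s in range(1, residues_per_chain + 1)]
    buried_set = {
        flat[int(i)]
        for i in rng.choice(total, size=n_buried, replace=False)
    }

    n_exposed = total - n_buried
    ring_radius = max(25.0, 12.0 * max(n_exposed, 1) / (2 * np.pi))
    angles = 2 * np.pi * np.arange(max(n_exposed, 1)) / max(n_exposed, 1)
    angles = angles + rng.uniform(-0.02, 0.02, size=angles.size)

    cage_dirs = sphere_points(_CAGE_POINTS)
    labels: dict[str, dict[str, str]] = {cid: {} for cid in chain_ids}
    chains: list[Chain] = []
    cage_residues: list[Residue] = []
    i_exposed = 0
    i_buried = 0
    for cid in chain_ids:
        residues = []
        for s in range(1, residues_per_chain + 1):
            if (cid, s) in buried_set:
                site = np.array([0.0, 0.0, 40.0 + 18.0 * i_buried])
                residues.append(
                    Residue(
                        seq_index=s,
                        name="ALA",
                        atoms=[Atom(name="CA", element="C", x=site[0], y=site[1], z=site[2])],
                        plddt=90.0,
                    )
                )
                cage_atoms = [
                    Atom(
                        name=f"C{k + 1}",
                        element="C",
                        x=site[0] + _CAGE_RADIUS * d[0],
                        y=site[1] + _CAGE_RADIUS * d[1],
                        z=site[2] + _CAGE_RADIUS * d[2],
                    )
                    for k, d in enumerate(cage_dirs)
                ]
                cage_residues.append(
                    Residue(seq_index=i_buried + 1, name="ALA", atoms=cage_atoms, plddt=90.0)
                )
                labels[cid][str(s)] = "buried"
                i_buried += 1
            else:
                a = angles[i_exposed]
                center = np.array([ring_radius * np.cos(a), ring_radius * np.sin(a), 0.0])
                residues.append(
                    Residue(seq_index=s, name="ALA", atoms=_cluster(center, +1.0), plddt=90.0)
                )
                labels[cid][str(s)] = "exposed"
                i_exposed += 1
        chains.append(Chain(chain_id=cid, residues=residues))
    if cage_residues:
        chains.append(Chain(chain_id=_CAGE_CHAIN, residues=cage_residues))

    model = StructureModel(model_id=model_id, chains=chains)
    truth = ComplexGroundTruth(
        labels=labels,
        buried_fraction=buried_fraction,
        seed=seed,
        params={"n_chains": n_chains, "residues_per_chain": residues_per_chain},
    )
    if validate:
        sasa = compute_sasa(model)
        for cid, per in labels.items():
            for seq, lab in per.items():
                rsa = relative_sasa(sasa.residue_sasa[(cid, int(seq))], "ALA")
                if lab == "buried" and rsa >= 0.05:
                    raise RuntimeError(
                        f"construction check failed: buried {cid}/{seq} has rSASA {rsa:.3f}"
                    )
                if lab == "exposed" and rsa <= 0.5:
                    raise RuntimeError(
                        f"construction check failed: exposed {cid}/{seq} has rSASA {rsa:.3f}"
                    )
    return model, truth


# --------------------------------------------------------------------------
# division-plane image stacks

@dataclass
class StackGroundTruth:
    pattern: str
    cell_radius_um: float
    center_px: float  # image centre (same for y and x)
    peak_intensity: float
    second_channel_offset_um: float | None
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        _write_json(dataclasses.asdict(self), path)


def division_pattern_mask(
    pattern: str,
    n_pix: int,
    pixel_size_um: float,
    cell_radius_um: float,
    x_offset_um: float = 0.0,
    ring_width_um: float = 0.15,
    disk_radius_fraction: float = 0.5,
) -> np.ndarray:
    """Analytic end-on division-plane mask in [0, 1].

    ``ring``: Gaussian annulus at the cell radius (signal on the rim);
    ``disk``: Gaussian disk over the plane centre (signal spread inwards);
    ``ring_plus_disk``: their mean.
    """
    c = (n_pix - 1) / 2.0
    y, x = np.mgrid[0:n_pix, 0:n_pix]
    xu = (x - c) * pixel_size_um - x_offset_um
    yu = (y - c) * pixel_size_um
    rho = np.hypot(xu, yu)
    ring = np.exp(-((rho - cell_radius_um) ** 2) / (2 * ring_width_um**2))
    disk = np.exp(-(rho**2) / (2 * (disk_radius_fraction * cell_radius_um) ** 2))
    if pattern == "ring":
        return ring
    if pattern == "disk":
        return disk
    if pattern == "ring_plus_disk":
        return 0.5 * (ring + disk)
    raise ValueError(f"unknown pattern {pattern!r}")


def make_division_stack(
    pattern: str = "ring",
    cell_radius_um: float = 1.8,
    pixel_size_um: float = 0.1,
    z_step_um: float = 0.5,
    n_z: int = 7,
    psf_sigma_um: float = 0.0,
    peak_intensity: float = 200.0,
    poisson_noise: bool = False,
    second_channel_offset_um: float | None = None,
    ring_width_um: float = 0.15,
    disk_radius_fraction: float = 0.5,
    seed: int = 0,
) -> tuple[ImageStack, StackGroundTruth]:
    """End-on division-plane stack with a planted ring or disk geometry.

    Intensity is the analytic mask scaled to ``peak_intensity``, weighted
    along z by a Gaussian centred on the middle slice (sigma one slice),
    optionally blurred by a Gaussian PSF and Poisson-resampled.  A second
    channel with the same pattern shifted ``second_channel_offset_um``
    along x is added when the offset is given.
    """
    rng = np.random.default_rng(seed)
    margin_um = 0.6
    half = cell_radius_um + margin_um
    n_pix = 2 * int(round(half / pixel_size_um)) + 1
    zc = (n_z - 1) / 2.0
    z_weight = np.exp(-((np.arange(n_z) - zc) ** 2) / 2.0)

    offsets = [0.0]
    channels = ["ch1"]
    if second_channel_offset_um is not None:
        offsets.append(second_channel_offset_um)
        channels.append("ch2")

    data = np.empty((len(offsets), n_z, n_pix, n_pix))
    for ci, off in enumerate(offsets):
        mask = division_pattern_mask(
            pattern,
            n_pix,
            pixel_size_um,
            cell_radius_um,
            x_offset_um=off,
            ring_width_um=ring_width_um,
            disk_radius_fraction=disk_radius_fraction,
        )
        plane = peak_intensity * mask
        for zi in range(n_z):
            img = plane * z_weight[zi]
            if psf_sigma_um > 0:
                img = ndimage.gaussian_filter(img, psf_sigma_um / pixel_size_um)
            data[ci, zi] = img
    if poisson_noise:
        data = rng.poisson(data).astype(float)

    stack = ImageStack(
        data=data,
        pixel_size_um=pixel_size_um,
        z_step_um=z_step_um,
        channels=channels,
    )
    truth = StackGroundTruth(
        pattern=pattern,
        cell_radius_um=cell_radius_um,
        center_px=(n_pix - 1) / 2.0,
        peak_intensity=peak_intensity,
        second_channel_offset_um=second_channel_offset_um,
        seed=seed,
        params={
            "pixel_size_um": pixel_size_um,
            "z_step_um": z_step_um,
            "n_z": n_z,
            "psf_sigma_um": psf_sigma_um,
            "poisson_noise": poisson_noise,
            "ring_width_um": ring_width_um,
            "disk_radius_fraction": disk_radius_fraction,
        },
    )
    return stack, truth


# --------------------------------------------------------------------------
# FRAP traces

@dataclass
class FrapGroundTruth:
    """Planted kinetics plus the parameters expected after normalization.

    The planted recovery is expressed on the pre-bleach=100 scale; the
    normalization step maps mean pre-bleach -> 100 and first post-bleach
    -> 0, which transforms (m1, m2) affinely while leaving m3 untouched.
    ``expected_normalized`` holds the (m1, m2, m3) the pipeline should
    recover from the normalized series.
    """

    m1: float
    m2: float
    m3: float
    acquisition_bleach_rate: float
    background_level: float
    noise_sd: float
    prebleach_level: float
    expected_normalized: tuple[float, float, float]
    seed: int
    params: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["expected_normalized"] = list(self.expected_normalized)
        _write_json(d, path)


def make_frap_trace(
    m1: float = 80.0,
    m2: float = -80.0,
    m3: float = 0.1,
    dt: float = 0.33,
    n_pre: int = 5,
    n_post: int = 150,
    acquisition_bleach_rate: float = 0.0,
    background_level: float = 50.0,
    noise_sd: float = 0.0,
    prebleach_level: float = 100.0,
    reference_level: float = 500.0,
    seed: int = 0,
) -> tuple[FRAPTrace, FrapGroundTruth]:
    """Forward-simulated FRAP trace.

    The bleach ROI carries the planted recovery ``m1 + m2*exp(-m3*t)``
    (pre-bleach frames at ``prebleach_level``), multiplied by a per-frame
    acquisition photobleaching decay shared with the reference ROI, plus a
    constant background and Gaussian noise.  Noiseless traces invert
    exactly through correct -> normalize.
    """
    if m1 + m2 >= prebleach_level:
        raise ValueError("first post-bleach level must lie below the pre-bleach level")
    rng = np.random.default_rng(seed)
    n_total = n_pre + n_post
    frames = np.arange(n_total)
    times = frames * dt
    t_post = (frames[n_pre:] - n_pre) * dt

    signal = np.empty(n_total)
    signal[:n_pre] = prebleach_level
    signal[n_pre:] = m1 + m2 * np.exp(-m3 * t_post)

    decay = np.exp(-acquisition_bleach_rate * frames)
    bleach = signal * decay + background_level
    reference = reference_level * decay + background_level
    background = np.full(n_total, background_level)
    if noise_sd > 0:
        bleach = bleach + rng.normal(0.0, noise_sd, n_total)
        reference = reference + rng.normal(0.0, noise_sd, n_total)
        background = background + rng.normal(0.0, noise_sd * 0.2, n_total)
    bleach = np.clip(bleach, 0.0, None)

    trace = FRAPTrace(
        times=times,
        bleach=bleach,
        reference=reference,
        background=background,
        n_prebleach=n_pre,
    )
    first_post = m1 + m2
    scale = 100.0 / (prebleach_level - first_post)
    truth = FrapGroundTruth(
        m1=m1,
        m2=m2,
        m3=m3,
        acquisition_bleach_rate=acquisition_bleach_rate,
        background_level=background_level,
        noise_sd=noise_sd,
        prebleach_level=prebleach_level,
        expected_normalized=((m1 - first_post) * scale, m2 * scale, m3),
        seed=seed,
        params={"dt": dt, "n_pre": n_pre, "n_post": n_post, "reference_level": reference_level},
    )
    return trace, truth
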