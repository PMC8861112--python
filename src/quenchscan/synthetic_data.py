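"""Synthetic fixtures with exact ground truth for every pipeline stage.

Generates (i) dual-channel microscopy fields with elliptical cells whose
membrane YFP enrichment realizes planted ρ values, (ii) quench traces from
the forward kinetic model plus Gaussian noise, (iii) whole screen datasets
(plates × variants × conditions) and (iv) toy coordinate trajectories with
planted conformational clusters, χ1 rotamer schedules and hydrogen-bond
occupancy. Every planted quantity is recorded in a manifest; recovery tests
compare pipeline output against the manifest and nothing else.

Reproducibility: a single master seed spawns a per-object child stream via
``child_rng(master, *keys)``, which hashes the key strings with CRC-32 and
feeds (master, crc(key0), crc(key1), ...) to ``numpy.random.default_rng``.
The scheme is stable across runs and platforms.
"""

from __future__ import annotations

import math
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .image_quant import DEFAULT_PIXEL_SIZE, ImagePair
from .quench_model import ProtocolSpec, QuenchModelParams, simulate_trace, standard_protocol
from .trace_fit import QuenchTrace

__all__ = [
    "child_rng",
    "VariantSpec",
    "PlateSpec",
    "PlateDataset",
    "make_image_pair",
    "make_trace",
    "make_plate",
    "make_trajectory",
    "screen_variants",
]


def child_rng(master_seed: int, *keys) -> np.random.Generator:
    """Deterministic per-object random stream derived from the master seed."""
    words = [int(master_seed) & 0x7FFFFFFF]
    for k in keys:
        words.append(zlib.crc32(str(k).encode()) & 0x7FFFFFFF)
    return np.random.default_rng(words)


# ---------------------------------------------------------------------------
# images


def _draw_ellipse_mask(shape, center, axes, rng) -> np.ndarray:
    yy, xx = np.mgrid[0: shape[0], 0: shape[1]]
    cy, cx = center
    a, b = axes
    theta = rng.uniform(0, math.pi)
    dx = xx - cx
    dy = yy - cy
    xr = dx * math.cos(theta) + dy * math.sin(theta)
    yr = -dx * math.sin(theta) + dy * math.cos(theta)
    return (xr / a) ** 2 + (yr / b) ** 2 <= 1.0


def make_image_pair(
    n_cells: int,
    rho_values=None,
    *,
    pixel_size: float = DEFAULT_PIXEL_SIZE,
    seed: int = 0,
    shape: tuple[int, int] = (384, 384),
    background: float = 100.0,
    amplitude: float = 1000.0,
    band_width: float = 1.08,
    read_noise_sd: float = 2.0,
    shot_noise: bool = True,
    expression_scale: float = 1.0,
    max_tries: int = 2000,
    genotype: str = "WT",
    plate: str = "P1",
) -> tuple[ImagePair, dict]:
    """One synthetic dual-channel field with ``n_cells`` non-overlapping
    elliptical cells.

    mCherry is uniform within each cell; YFP is split between a membrane band
    (same 1.08 µm definition the analysis uses) and the interior so that each
    cell's measured ρ equals its planted value from ``rho_values`` (default:
    all 1.0, i.e. uniform YFP). Poisson shot noise and Gaussian read noise
    are added on a constant background. The manifest records every planted
    geometry, amplitude and ρ.
    """
    from scipy import ndimage as ndi

    if n_cells < 0:
        raise ValueError("n_cells must be non-negative")
    rng = child_rng(seed, "image_pair", plate, genotype)
    if rho_values is None:
        rho_values = np.ones(n_cells)
    rho_values = np.asarray(rho_values, dtype=float)
    if rho_values.size != n_cells:
        raise ValueError("rho_values must have one entry per cell")

    occupied = np.zeros(shape, dtype=bool)
    mch = np.zeros(shape, dtype=float)
    yfp = np.zeros(shape, dtype=float)
    cells = []
    margin = 6
    band_px = max(int(round(band_width / pixel_size)), 1)

    for i in range(n_cells):
        placed = False
        for _ in range(max_tries):
            # equivalent radius 7-12 um: passes the default geometry QC
            r_um = rng.uniform(7.0, 12.0)
            ecc = rng.uniform(0.75, 1.0)
            a = r_um / math.sqrt(ecc) / pixel_size
            b = r_um * math.sqrt(ecc) / pixel_size
            cy = rng.uniform(a + margin, shape[0] - a - margin)
            cx = rng.uniform(a + margin, shape[1] - a - margin)
            mask = _draw_ellipse_mask(shape, (cy, cx), (a, b), rng)
            grown = ndi.binary_dilation(mask, iterations=3)
            if not (grown & occupied).any():
                placed = True
                break
        if not placed:
            raise RuntimeError(f"could not place cell {i} without overlap")
        occupied |= ndi.binary_dilation(mask, iterations=2)

        interior = ndi.distance_transform_edt(mask) > band_px
        band = mask & ~interior
        m_amp = amplitude * expression_scale
        rho = float(rho_values[i])
        band_amp = rho * m_amp
        if interior.any() and band.any():
            interior_amp = min(band_amp, m_amp)  # enrichment never below interior
            if rho <= 1.0:
                interior_amp = band_amp  # uniform when no enrichment is asked
            yfp[band] += band_amp
            yfp[interior] += interior_amp
            mean_cell_yfp = (band_amp * band.sum() + interior_amp * interior.sum()) / mask.sum()
        else:
            yfp[mask] += band_amp
            mean_cell_yfp = band_amp
        mch[mask] += m_amp
        cells.append({
            "center": (float(cy), float(cx)),
            "axes_px": (float(a), float(b)),
            "area_um2": float(mask.sum()) * pixel_size**2,
            "rho": rho,
            "band_amplitude": band_amp,
            "mcherry_amplitude": m_amp,
            "mean_cell_yfp": float(mean_cell_yfp),
        })

    def finish(img):
        img = img + background
        if shot_noise:
            img = rng.poisson(img).astype(float)
        img = img + rng.normal(0.0, read_noise_sd, shape)
        return np.clip(img, 0, 65535).astype(np.uint16)

    pair = ImagePair(
        mcherry=finish(mch), yfp=finish(yfp), pixel_size=pixel_size,
        plate=plate, genotype=genotype,
    )
    manifest = {
        "n_cells": n_cells, "background": background, "amplitude": amplitude,
        "pixel_size": pixel_size, "band_width": band_width, "cells": cells,
    }
    return pair, manifest


# ---------------------------------------------------------------------------
# traces


def make_trace(
    params: QuenchModelParams,
    protocol: ProtocolSpec | None = None,
    noise_sd: float = 0.01,
    seed: int = 0,
    *,
    scale: float = 3000.0,
    vm_mode: str = "fixed",
    plate: str = "P1",
    well: str = "A01",
    genotype: str = "WT",
    condition: str = "forskolin",
) -> tuple[QuenchTrace, dict]:
    """One raw-intensity quench trace from the forward model.

    The model's baseline-normalized anion-free fraction is scaled to a raw
    baseline of ``scale`` counts; i.i.d. Gaussian noise with standard
    deviation ``noise_sd``·baseline is added. The manifest stores the
    generating parameters.
    """
    protocol = protocol or standard_protocol(condition != "DMSO")
    rng = child_rng(seed, "trace", plate, well)
    pred = simulate_trace(params, protocol, vm_mode=vm_mode)
    raw = scale * pred.normalized()
    if noise_sd > 0:
        raw = raw + rng.normal(0.0, noise_sd * scale, raw.size)
    trace = QuenchTrace(
        times=pred.times, fluorescence=raw,
        addition_times=protocol.addition_times(),
        plate=plate, well=well, genotype=genotype, condition=condition,
    )
    manifest = {
        "Vm": params.Vm, "G": params.G, "G_trans": params.G_trans,
        "tau_trans": params.tau_trans, "noise_sd": noise_sd, "scale": scale,
        "vm_mode": vm_mode,
    }
    return trace, manifest


# ---------------------------------------------------------------------------
# plates / screens


@dataclass(frozen=True)
class VariantSpec:
    """Ground-truth behaviour of one CFTR variant in the screen."""

    name: str
    g_fsk: float           # nS, median forskolin-stimulated conductance
    g_dmso: float = 1.0    # nS, basal conductance under DMSO
    vm: float = -40.0      # mV
    log10_rho_mean: float = 0.0
    log10_rho_sd: float = 0.12
    expression_scale: float = 1.0


@dataclass(frozen=True)
class PlateSpec:
    """Layout of a simulated screen: which variants, how many wells per
    condition per plate, how many plates, and the noise levels."""

    variants: tuple[VariantSpec, ...]
    wells_per_condition: int = 5
    plates: int = 4
    cells_per_well: int = 30
    trace_noise_sd: float = 0.01
    g_well_cv: float = 0.3     # lognormal well-to-well spread of true G
    vm_well_sd: float = 4.0    # mV well-to-well spread of true Vm
    wt_name: str = "WT"
    reference_name: str = "F508del"

    def __post_init__(self) -> None:
        if self.wells_per_condition < 1 or self.plates < 1:
            raise ValueError("need at least one well and one plate")
        names = [v.name for v in self.variants]
        if self.wt_name not in names:
            raise ValueError("spec must include a WT variant (plate normalization)")
        if len(set(names)) != len(names):
            raise ValueError("duplicate variant names")


@dataclass
class PlateDataset:
    """Everything a simulated screen produced, plus its ground truth."""

    platemap: pd.DataFrame     # plate, well, variant, condition, true_G, true_Vm
    traces: list[QuenchTrace]
    rho_cells: pd.DataFrame    # plate, variant, cell, rho
    manifest: dict
    images: list = field(default_factory=list)


def screen_variants(
    effect: float = 0.0,
    n_test_variants: int = 4,
    rho_effect: float = 0.0,
) -> tuple[VariantSpec, ...]:
    """Convenience screen layout: WT, F508del, and test variants whose
    forskolin conductance is F508del's times ``(1 + effect)`` and whose mean
    log10 ρ is shifted by ``rho_effect``. ``effect=0`` is the null screen."""
    base = [
        VariantSpec("WT", g_fsk=117.7, g_dmso=2.35, vm=-40.0, log10_rho_mean=0.0),
        VariantSpec("F508del", g_fsk=5.7, g_dmso=0.86, vm=-20.0, log10_rho_mean=-0.8),
    ]
    for i in range(n_test_variants):
        base.append(VariantSpec(
            f"F508del/M{i + 1}", g_fsk=5.7 * (1.0 + effect), g_dmso=0.86,
            vm=-20.0, log10_rho_mean=-0.8 + rho_effect,
        ))
    return tuple(base)


def make_plate(
    spec: PlateSpec,
    seed: int = 0,
    *,
    protocol_fsk: ProtocolSpec | None = None,
    protocol_dmso: ProtocolSpec | None = None,
    fidelity: str = "summary",
    conditions: tuple[str, ...] = ("DMSO", "forskolin"),
) -> PlateDataset:
    """Simulate a full screen dataset from a PlateSpec.

    Per plate, variant and condition, ``wells_per_condition`` wells each get
    a quench trace generated from the variant's true (V_m, G) with
    well-to-well lognormal spread on G; per plate and variant,
    ``cells_per_well`` cells get ρ values drawn from the variant's planted
    log10-normal distribution. ``fidelity="images"`` additionally renders one
    image field per plate×variant realizing those ρ values (slow; meant for
    image-pipeline checks). Identical (spec, seed) give identical datasets.
    """
    if fidelity not in ("summary", "images"):
        raise ValueError("fidelity must be 'summary' or 'images'")
    protocol_fsk = protocol_fsk or standard_protocol(True)
    protocol_dmso = protocol_dmso or standard_protocol(False)

    rows, traces, rho_rows, images = [], [], [], []
    manifest: dict = {"wells": {}, "rho": {}, "spec_seed": seed}
    for p in range(spec.plates):
        plate = f"P{p + 1}"
        for var in spec.variants:
            for cond in conditions:
                g_true = var.g_fsk if cond == "forskolin" else var.g_dmso
                proto = protocol_fsk if cond == "forskolin" else protocol_dmso
                for w in range(spec.wells_per_condition):
                    well = f"{var.name}-{cond}-{w}"
                    rng = child_rng(seed, "well", plate, well)
                    g_well = g_true * rng.lognormal(0.0, spec.g_well_cv)
                    vm_well = min(var.vm + rng.normal(0.0, spec.vm_well_sd), -1.0)
                    params = QuenchModelParams(Vm=vm_well, G=g_well)
                    trace, _ = make_trace(
                        params, proto, spec.trace_noise_sd,
                        seed, plate=plate, well=well,
                        genotype=var.name, condition=cond,
                    )
                    traces.append(trace)
                    rows.append({
                        "plate": plate, "well": well, "variant": var.name,
                        "condition": cond, "true_G": g_well, "true_Vm": vm_well,
                        "expression_scale": var.expression_scale,
                    })
                    manifest["wells"][f"{plate}/{well}"] = {
                        "G": g_well, "Vm": vm_well, "condition": cond,
                    }
            rng_rho = child_rng(seed, "rho", plate, var.name)
            log_rho = rng_rho.normal(var.log10_rho_mean, var.log10_rho_sd,
                                     spec.cells_per_well)
            for ci, lr in enumerate(log_rho):
                rho_rows.append({
                    "plate": plate, "variant": var.name, "cell": ci,
                    "rho": float(10.0 ** lr),
                })
            manifest["rho"][f"{plate}/{var.name}"] = {
                "log10_mean": var.log10_rho_mean, "log10_sd": var.log10_rho_sd,
                "values": (10.0 ** log_rho).tolist(),
            }
            if fidelity == "images":
                pair, man = make_image_pair(
                    min(spec.cells_per_well, 12),
                    rho_values=10.0 ** log_rho[: min(spec.cells_per_well, 12)],
                    seed=seed, plate=plate, genotype=var.name,
                    expression_scale=var.expression_scale,
                )
                images.append(pair)
                manifest["rho"][f"{plate}/{var.name}"]["image_manifest"] = man

    return PlateDataset(
        platemap=pd.DataFrame(rows), traces=traces,
        rho_cells=pd.DataFrame(rho_rows), manifest=manifest, images=images,
    )


# ---------------------------------------------------------------------------
# trajectories


def _place_by_internal(a, b, c, bond: float, angle: float, dihedral_deg: float):
    """Place atom d given three predecessors using internal coordinates
    (NeRF construction): |cd| = bond, angle b-c-d, dihedral a-b-c-d."""
    a, b, c = (np.asarray(p, dtype=float) for p in (a, b, c))
    ang = math.radians(angle)
    dih = math.radians(dihedral_deg)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


def make_trajectory(
    cluster_plan=(1.0,),
    rotamer_schedule: dict | None = None,
    hbond_schedule: list | None = None,
    n_frames: int = 50,
    seed: int = 0,
    *,
    n_residues: int = 12,
    first_res_id: int = 495,
    conformer_sd: float = 0.08,
    jitter_sd: float = 0.004,
    frame_spacing: float = 500.0,
):
    """Toy trajectory with planted clusters, rotamers and hydrogen bonds.

    A poly-residue chain (backbone N, CA, C, O, amide H; side-chain CB, CG)
    is built along x. ``cluster_plan`` gives conformer populations (must sum
    to 1); each conformer is the base chain plus a fixed random deformation
    of per-atom sd ``conformer_sd`` nm (inter-conformer RMSD well above the
    0.1 nm clustering cutoff), and every frame adds jitter of sd
    ``jitter_sd`` nm (intra-conformer RMSD well below it).

    ``rotamer_schedule`` maps res_id → per-frame χ1 array or a list of
    (angle, fraction) modes; CG is placed exactly at the scheduled dihedral
    after deformation. ``hbond_schedule`` entries are dicts with keys
    ``donor_res``, ``acceptor_res`` and ``frames`` (boolean array or index
    list): in scheduled frames the acceptor's O sits 0.29 nm from the
    donor's N along the N–H direction; otherwise 0.50 nm away.

    Returns (Trajectory, manifest).
    """
    from .md_metrics import Trajectory

    pops = np.asarray(cluster_plan, dtype=float)
    if pops.size == 0 or abs(pops.sum() - 1.0) > 1e-9 or np.any(pops < 0):
        raise ValueError("cluster populations must be non-negative and sum to 1")
    rng = child_rng(seed, "trajectory")

    res_ids = list(range(first_res_id, first_res_id + n_residues))
    atom_rows = []
    base_pos = []
    spacing = 0.55
    for i, rid in enumerate(res_ids):
        x = i * spacing
        n_pos = np.array([x, 0.0, 0.0])
        ca = np.array([x + 0.145, 0.03, 0.0])
        c = np.array([x + 0.29, -0.03, 0.0])
        o = c + np.array([0.02, -0.12, 0.0])
        h = n_pos + np.array([-0.06, 0.08, 0.0])
        cb = ca + np.array([0.0, 0.14, 0.05])
        cg = _place_by_internal(n_pos, ca, cb, 0.15, 111.0, 300.0)
        for name, pos in (("N", n_pos), ("H", h), ("CA", ca), ("C", c),
                          ("O", o), ("CB", cb), ("CG", cg)):
            atom_rows.append({"res_id": rid, "res_name": "PHE",
                              "atom_name": name, "chain": "A"})
            base_pos.append(pos)
    atoms = pd.DataFrame(atom_rows)
    base = np.array(base_pos)
    n_atoms = base.shape[0]
    name_arr = atoms["atom_name"].to_numpy()
    rid_arr = atoms["res_id"].to_numpy()

    def idx_of(rid, name):
        hits = np.flatnonzero((rid_arr == rid) & (name_arr == name))
        if hits.size == 0:
            raise ValueError(f"no atom {name} in residue {rid}")
        return int(hits[0])

    # exact conformer counts by largest remainder, then a seeded shuffle
    counts = np.floor(pops * n_frames).astype(int)
    for k in np.argsort(-(pops * n_frames - counts))[: n_frames - counts.sum()]:
        counts[k] += 1
    conformer_of_frame = np.repeat(np.arange(pops.size), counts)
    rng.shuffle(conformer_of_frame)

    deformations = [
        rng.normal(0.0, conformer_sd, (n_atoms, 3)) if k > 0 else np.zeros((n_atoms, 3))
        for k in range(pops.size)
    ]

    chi_of_frame: dict[int, np.ndarray] = {}
    if rotamer_schedule:
        for rid, sched in rotamer_schedule.items():
            if isinstance(sched, (list, tuple)) and isinstance(sched[0], (list, tuple)):
                modes = np.array([m[0] for m in sched])
                fracs = np.array([m[1] for m in sched], dtype=float)
                fracs /= fracs.sum()
                cnt = np.floor(fracs * n_frames).astype(int)
                for k in np.argsort(-(fracs * n_frames - cnt))[: n_frames - cnt.sum()]:
                    cnt[k] += 1
                vals = np.repeat(modes, cnt).astype(float)
                rng.shuffle(vals)
            else:
                vals = np.asarray(sched, dtype=float)
                if vals.size != n_frames:
                    raise ValueError("per-frame chi1 schedule length mismatch")
            chi_of_frame[rid] = vals

    hbond_schedule = hbond_schedule or []
    hb_manifest = []
    coords = np.empty((n_frames, n_atoms, 3))
    for f in range(n_frames):
        frame = base + deformations[conformer_of_frame[f]]
        frame = frame + rng.normal(0.0, jitter_sd, (n_atoms, 3))
        for rid, vals in chi_of_frame.items():
            i_n, i_ca, i_cb, i_cg = (idx_of(rid, nm) for nm in ("N", "CA", "CB", "CG"))
            frame[i_cg] = _place_by_internal(
                frame[i_n], frame[i_ca], frame[i_cb], 0.15, 111.0, float(vals[f])
            )
        for hb in hbond_schedule:
            i_d = idx_of(hb["donor_res"], "N")
            i_h = idx_of(hb["donor_res"], "H")
            i_a = idx_of(hb["acceptor_res"], "O")
            u = frame[i_h] - frame[i_d]
            u /= np.linalg.norm(u)
            present = f in set(np.flatnonzero(hb["frames"])) \
                if not isinstance(hb["frames"], (set, list)) else f in set(hb["frames"])
            frame[i_a] = frame[i_d] + (0.29 if present else 0.50) * u
        coords[f] = frame

    for hb in hbond_schedule:
        frames = hb["frames"]
        occ = np.zeros(n_frames, dtype=bool)
        if isinstance(frames, (set, list)):
            occ[list(frames)] = True
        else:
            occ[np.flatnonzero(frames)] = True
        hb_manifest.append({
            "donor": idx_of(hb["donor_res"], "N"),
            "hydrogen": idx_of(hb["donor_res"], "H"),
            "acceptor": idx_of(hb["acceptor_res"], "O"),
            "occupancy": occ,
        })

    traj = Trajectory(coords=coords, atoms=atoms, frame_spacing=frame_spacing)
    manifest = {
        "populations": pops.tolist(),
        "conformer_of_frame": conformer_of_frame.copy(),
        "chi1": {rid: vals.copy() for rid, vals in chi_of_frame.items()},
        "hbonds": hb_manifest,
        "res_ids": res_ids,
    }
    return traj, manifest
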