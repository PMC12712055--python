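"""Ground-truth-annotated synthetic inputs for every pipeline stage.

The MINFLUX generator emulates the localization tables a 3D-MINFLUX /
DNA-PAINT experiment on ALFA-tagged trimeric PIEZO1 exports: trimers are
planar triangles whose side length follows the conformational interblade
distribution, each labelled protomer produces repeated binding traces, each
trace a burst of localizations with per-axis precision noise, plus a fixed
label-linkage offset, out-of-plane z offsets, uniform background traces and
a fraction of multi-emitter-contaminated traces carrying high cfr/efo
values.  Emitted z is pre-divided by the refractive-index factor 0.7 so the
pipeline's documented z x 0.7 correction is exercised rather than bypassed.

Generation starts at the "valid localization" level: no photophysics,
photon budgets or iteration-level MINFLUX simulation.

Electrophysiology, calcium-imaging and docking-pose fixtures are generated
by the remaining functions; each fit in :mod:`piezoflux.functional_fits`
recovers its generator's parameters exactly on noiseless input.

All generators are deterministic given their seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .functional_fits import SweepSeries, boltzmann, logistic4
from .pose_contacts import PoseEnsemble

_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS", "Q": "GLN",
    "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE", "L": "LEU", "K": "LYS",
    "M": "MET", "F": "PHE", "P": "PRO", "S": "SER", "T": "THR", "W": "TRP",
    "Y": "TYR", "V": "VAL",
}

#: Physical upper bound (nm) on the tag-tag distance of a fully flattened trimer.
MAX_PAIR_DISTANCE_NM = 40.0


@dataclass(frozen=True)
class SynthMinfluxConfig:
    """Study conditions for the synthetic MINFLUX dataset.

    Defaults emulate the imaging regime of a 3 x 3 um ROI of a PIEZO1-ALFA
    expressing cell: interblade distances around 21.7 +- 5.5 nm (curved-state
    population), ~2 nm per-axis localization precision, ~2.5 nm 3D linkage
    error (1.5 nm per axis), a 10% multi-emitter trace fraction and one
    nonspecific background trace per um^2.  Labeling efficiency and
    background density are free parameters of the experiment and are not
    constrained by published values.
    """

    n_trimers: int = 100
    field_size: float = 3000.0  # nm, x/y extent of the ROI
    interblade_mean: float = 21.7  # nm
    interblade_sd: float = 5.5  # nm
    label_efficiency: float = 0.9  # probability a protomer carries a label
    traces_per_label: float = 3.0  # Poisson mean, floored at 1
    locs_per_trace: float = 8.0  # Poisson mean, floored at 3
    loc_sd: float = 2.0  # nm per axis
    linkage_sd: float = 1.5  # nm per axis (isotropic 3D label offset)
    z_plane_sd: float = 5.0  # nm, z offset of each trimer plane
    background_trace_density: float = 1.0  # traces per um^2
    multi_emitter_fraction: float = 0.1
    cfr_clean: tuple[float, float] = (0.4, 0.15)  # (mean, sd), clipped <= 0.8
    cfr_dirty: tuple[float, float] = (0.92, 0.05)  # clipped > 0.8
    efo_clean: tuple[float, float] = (60.0, 15.0)  # kHz
    efo_dirty: tuple[float, float] = (250.0, 50.0)  # kHz
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "field_size", "interblade_mean", "interblade_sd", "traces_per_label",
            "locs_per_trace", "loc_sd", "linkage_sd", "z_plane_sd",
            "background_trace_density",
        ):
            v = float(getattr(self, name))
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {v}")
        if self.interblade_mean <= 0 or self.field_size <= 0:
            raise ValueError("interblade_mean and field_size must be positive")
        for name in ("label_efficiency", "multi_emitter_fraction"):
            v = float(getattr(self, name))
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be a probability in [0, 1], got {v}")
        for name in ("cfr_clean", "cfr_dirty", "efo_clean", "efo_dirty"):
            pair = getattr(self, name)
            if len(pair) != 2 or not np.all(np.isfinite(pair)):
                raise ValueError(f"{name} must be a finite (mean, sd) pair")
        if self.n_trimers < 0:
            raise ValueError("n_trimers must be >= 0")


@dataclass
class GroundTruth:
    """Bookkeeping of what was generated, for pipeline validation.

    ``trimers`` carries the true centroid and the true interblade distance
    (mean of the three pairwise distances between the true fluorophore
    positions, linkage offset included); ``protomers`` the true positions and
    labelled flags; ``traces`` each trace's origin (protomer index or
    background) and contamination flag.
    """

    trimers: pd.DataFrame  # trimer_id, cx, cy, cz, interblade_nm, n_labeled
    protomers: pd.DataFrame  # trimer_id, protomer, x_nm, y_nm, z_nm, labeled
    traces: pd.DataFrame  # tid, origin, trimer_id, protomer, contaminated

    def check(self) -> None:
        """Assert internal consistency (one entry per trimer, distance identity)."""
        from .trimer_geometry import interblade_distance

        assert self.trimers["trimer_id"].is_unique
        for tri_id, grp in self.protomers.groupby("trimer_id"):
            pos = grp.sort_values("protomer")[["x_nm", "y_nm", "z_nm"]].to_numpy()
            truth = self.trimers.set_index("trimer_id").loc[tri_id, "interblade_nm"]
            assert abs(interblade_distance(pos) - truth) < 1e-9


def _truncated_normal(rng, mean, sd, low, high):
    """Draw one Normal(mean, sd) truncated to (low, high] by redraw."""
    if sd == 0:
        if not (low < mean <= high):
            raise ValueError(f"degenerate draw {mean} outside ({low}, {high}]")
        return mean
    for _ in range(10000):
        v = rng.normal(mean, sd)
        if low < v <= high:
            return v
    raise RuntimeError("truncated normal rejection did not converge")


def _place_trimer(rng, centroid, config) -> tuple[np.ndarray, float]:
    """True fluorophore positions (3, 3) and true interblade distance (nm)."""
    side = _truncated_normal(
        rng, config.interblade_mean, config.interblade_sd, 0.0, MAX_PAIR_DISTANCE_NM
    )
    theta0 = rng.uniform(0.0, 2.0 * np.pi)
    radius = side / np.sqrt(3.0)
    angles = theta0 + np.array([0.0, 2.0, 4.0]) * np.pi / 3.0
    verts = np.column_stack(
        [
            centroid[0] + radius * np.cos(angles),
            centroid[1] + radius * np.sin(angles),
            np.full(3, centroid[2]),
        ]
    )
    for _ in range(10000):
        pos = verts + rng.normal(0.0, config.linkage_sd, (3, 3))
        d = [
            np.linalg.norm(pos[a] - pos[b])
            for a, b in ((0, 1), (0, 2), (1, 2))
        ]
        if 0.0 < min(d) and max(d) <= MAX_PAIR_DISTANCE_NM:
            return pos, float(np.mean(d))
    raise RuntimeError("linkage-offset rejection did not converge")


def _quality_values(rng, n, dirty, config):
    """Per-localization cfr and efo draws for a clean or contaminated trace."""
    if dirty:
        cfr = np.clip(rng.normal(*config.cfr_dirty, n), 0.801, 1.5)
        efo = np.clip(rng.normal(*config.efo_dirty, n), 1.0, None)
    else:
        cfr = np.clip(rng.normal(*config.cfr_clean, n), 0.0, 0.8)
        efo = np.clip(rng.normal(*config.efo_clean, n), 1.0, None)
    return cfr, efo


def generate_minflux_dataset(
    config: SynthMinfluxConfig,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Generate a localization table plus its ground truth.

    Trimer centroids are placed on a jittered grid with 150 nm pitch so that
    by construction no two trimers violate each other's 60 nm isolation rule
    (background traces still can, as in a real sample).  Identical configs
    (including seed) give bit-identical tables.
    """
    config.__post_init__()  # re-validate in case of dataclasses.replace abuse
    rng = np.random.default_rng(config.seed)
    pitch = 150.0
    n_side = int(config.field_size // pitch)
    if n_side * n_side < config.n_trimers:
        raise ValueError(
            f"field_size {config.field_size} nm holds at most {n_side * n_side} "
            f"isolated trimers; asked for {config.n_trimers}"
        )
    cells = rng.choice(n_side * n_side, size=config.n_trimers, replace=False)
    cell_xy = np.column_stack([cells % n_side, cells // n_side]) * pitch + pitch / 2.0
    cell_xy = cell_xy + rng.normal(0.0, 10.0, cell_xy.shape)

    trimer_rows, protomer_rows, trace_rows = [], [], []
    loc_chunks: list[np.ndarray] = []
    loc_meta: list[tuple[int, int]] = []  # (tid, n_locs) per trace, in order
    cfr_chunks, efo_chunks = [], []
    next_tid = 1

    for tri_id in range(config.n_trimers):
        z_off = rng.normal(0.0, config.z_plane_sd)
        centroid = np.array([cell_xy[tri_id, 0], cell_xy[tri_id, 1], z_off])
        pos, true_d = _place_trimer(rng, centroid, config)
        labeled = rng.random(3) < config.label_efficiency
        trimer_rows.append(
            {
                "trimer_id": tri_id,
                "cx": centroid[0], "cy": centroid[1], "cz": centroid[2],
                "interblade_nm": true_d,
                "n_labeled": int(labeled.sum()),
            }
        )
        for p in range(3):
            protomer_rows.append(
                {
                    "trimer_id": tri_id, "protomer": p,
                    "x_nm": pos[p, 0], "y_nm": pos[p, 1], "z_nm": pos[p, 2],
                    "labeled": bool(labeled[p]),
                }
            )
            if not labeled[p]:
                continue
            k = max(1, int(rng.poisson(config.traces_per_label)))
            for _ in range(k):
                m = max(3, int(rng.poisson(config.locs_per_trace)))
                dirty = rng.random() < config.multi_emitter_fraction
                xyz = pos[p] + rng.normal(0.0, config.loc_sd, (m, 3))
                cfr, efo = _quality_values(rng, m, dirty, config)
                loc_chunks.append(xyz)
                cfr_chunks.append(cfr)
                efo_chunks.append(efo)
                loc_meta.append((next_tid, m))
                trace_rows.append(
                    {
                        "tid": next_tid, "origin": "protomer",
                        "trimer_id": tri_id, "protomer": p,
                        "contaminated": bool(dirty),
                    }
                )
                next_tid += 1

    area_um2 = (config.field_size / 1000.0) ** 2
    n_bg = int(rng.poisson(config.background_trace_density * area_um2))
    for _ in range(n_bg):
        origin = np.array(
            [
                rng.uniform(0.0, config.field_size),
                rng.uniform(0.0, config.field_size),
                rng.uniform(-50.0, 50.0),
            ]
        )
        m = max(3, int(rng.poisson(config.locs_per_trace)))
        dirty = rng.random() < config.multi_emitter_fraction
        xyz = origin + rng.normal(0.0, config.loc_sd, (m, 3))
        cfr, efo = _quality_values(rng, m, dirty, config)
        loc_chunks.append(xyz)
        cfr_chunks.append(cfr)
        efo_chunks.append(efo)
        loc_meta.append((next_tid, m))
        trace_rows.append(
            {
                "tid": next_tid, "origin": "background",
                "trimer_id": -1, "protomer": -1,
                "contaminated": bool(dirty),
            }
        )
        next_tid += 1

    if loc_chunks:
        xyz_all = np.concatenate(loc_chunks)
        tids = np.concatenate(
            [np.full(m, tid, dtype=np.int64) for tid, m in loc_meta]
        )
        cfr_all = np.concatenate(cfr_chunks)
        efo_all = np.concatenate(efo_chunks)
    else:
        xyz_all = np.empty((0, 3))
        tids = np.empty(0, dtype=np.int64)
        cfr_all = efo_all = np.empty(0)

    table = pd.DataFrame(
        {
            "tid": tids,
            "x_nm": xyz_all[:, 0],
            "y_nm": xyz_all[:, 1],
            # z exported pre-correction: the pipeline's z x 0.7 restores geometry
            "z_nm": xyz_all[:, 2] / 0.7,
            "cfr": cfr_all,
            "efo": efo_all,
            "t_s": np.arange(len(tids), dtype=float) * 1e-3,
        }
    )
    truth = GroundTruth(
        trimers=pd.DataFrame(
            trimer_rows,
            columns=["trimer_id", "cx", "cy", "cz", "interblade_nm", "n_labeled"],
        ),
        protomers=pd.DataFrame(
            protomer_rows,
            columns=["trimer_id", "protomer", "x_nm", "y_nm", "z_nm", "labeled"],
        ),
        traces=pd.DataFrame(
            trace_rows, columns=["tid", "origin", "trimer_id", "protomer", "contaminated"]
        ),
    )
    return table, truth


def write_minflux_dataset(
    table: pd.DataFrame, truth: GroundTruth, outdir: str | Path
) -> None:
    """Write the localization CSV plus ground-truth sidecar CSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    table.to_csv(outdir / "localizations.csv", index=False)
    truth.trimers.to_csv(outdir / "truth_trimers.csv", index=False)
    truth.protomers.to_csv(outdir / "truth_protomers.csv", index=False)
    truth.traces.to_csv(outdir / "truth_traces.csv", index=False)


# ---------------------------------------------------------------------------
# electrophysiology fixtures


def generate_pressure_sweeps(
    p50: float,
    slope: float,
    imax: float,
    pressures,
    noise_sd: float = 0.0,
    seed: int = 0,
    sample_rate_hz: float = 2000.0,
    stim_onset_s: float = 0.1,
    stim_duration_s: float = 0.5,
    total_s: float = 0.7,
) -> SweepSeries:
    """Pressure-clamp sweep family with Boltzmann peak amplitudes.

    The peak current of each sweep is ``imax / (1 + exp((P - p50)/slope))``
    plus one Gaussian noise draw per sweep (noise lives on the per-sweep peak
    amplitude, not on individual samples), applied as a square pulse over the
    stimulus window.
    """
    pressures = np.asarray(pressures, float)
    if len(pressures) == 0:
        raise ValueError("empty pressure list")
    rng = np.random.default_rng(seed)
    time_s = np.arange(0.0, total_s, 1.0 / sample_rate_hz)
    amps = imax * boltzmann(pressures, p50, slope)
    if noise_sd > 0:
        amps = amps + rng.normal(0.0, noise_sd, len(amps))
    in_stim = (time_s >= stim_onset_s) & (time_s < stim_onset_s + stim_duration_s)
    currents = np.outer(amps, in_stim.astype(float))
    return SweepSeries(
        stimuli=pressures,
        time_s=time_s,
        currents=currents,
        stim_onset_s=stim_onset_s,
        stim_duration_s=stim_duration_s,
        sample_rate_hz=sample_rate_hz,
        stimulus_unit="mmHg",
    )


def generate_current_decay(
    c1: float,
    c2: float,
    t0: float,
    tau_ms: float,
    rate_hz: float = 20000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    duration_s: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponentially decaying current ``C1 + C2 exp(-(t - t0)/tau)`` plus noise."""
    if tau_ms <= 0:
        raise ValueError("tau must be positive")
    tau_s = tau_ms * 1e-3
    if duration_s is None:
        duration_s = 8.0 * tau_s
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * rate_hz))
    t = t0 + np.arange(n) / rate_hz
    i = c1 + c2 * np.exp(-(t - t0) / tau_s)
    if noise_sd > 0:
        i = i + rng.normal(0.0, noise_sd, n)
    return t, i


@dataclass
class SingleChannelSeries:
    """Per-voltage two-level (closed/open) current traces."""

    voltages_mv: np.ndarray
    traces: dict[float, np.ndarray]  # voltage -> current samples (pA)
    sample_rate_hz: float
    conductance_ps: float
    reversal_mv: float


def generate_single_channel(
    voltages,
    conductance_ps: float = 40.0,
    reversal_mv: float = 0.0,
    open_prob: float = 0.3,
    seed: int = 0,
    sample_rate_hz: float = 5000.0,
    duration_s: float = 1.0,
    noise_sd_pa: float = 0.0,
    mean_open_s: float = 0.02,
) -> SingleChannelSeries:
    """Two-level single-channel traces obeying Ohm's law.

    The open-level offset at voltage V is ``conductance * (V - reversal) /
    1000`` pA; gating alternates exponential open/closed dwells whose means
    give the requested stationary open probability.
    """
    if conductance_ps <= 0:
        raise ValueError("conductance must be positive")
    if not (0.0 < open_prob < 1.0):
        raise ValueError("open_prob must be in (0, 1)")
    voltages = np.asarray(voltages, float)
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * sample_rate_hz))
    mean_closed_s = mean_open_s * (1.0 - open_prob) / open_prob
    traces = {}
    for v in voltages:
        level = conductance_ps * (v - reversal_mv) / 1000.0  # pA
        state = np.zeros(n, dtype=bool)
        idx = 0
        open_now = rng.random() < open_prob
        while idx < n:
            dwell_s = rng.exponential(mean_open_s if open_now else mean_closed_s)
            dwell = max(1, int(round(dwell_s * sample_rate_hz)))
            state[idx : idx + dwell] = open_now
            idx += dwell
            open_now = not open_now
        trace = state.astype(float) * level
        if noise_sd_pa > 0:
            trace = trace + rng.normal(0.0, noise_sd_pa, n)
        traces[float(v)] = trace
    return SingleChannelSeries(
        voltages_mv=voltages,
        traces=traces,
        sample_rate_hz=sample_rate_hz,
        conductance_ps=conductance_ps,
        reversal_mv=reversal_mv,
    )


# ---------------------------------------------------------------------------
# calcium-imaging fixtures


def generate_dose_response(
    ec50_um: float,
    hill: float,
    fmax: float,
    concentrations,
    n_cells: int = 50,
    noise_sd: float = 0.0,
    seed: int = 0,
    bottom: float = 1.0,
) -> pd.DataFrame:
    """Per-cell maximal F/F0 table following a 4-parameter logistic.

    The response at concentration c is
    ``bottom + (fmax - bottom) / (1 + (ec50/c)^hill)`` (the midpoint of
    bottom and fmax at c = ec50), plus cell-level Gaussian noise.
    Returns a long table with columns ``conc_um, cell, max_f_over_f0``.
    """
    if ec50_um <= 0:
        raise ValueError("ec50 must be positive")
    concentrations = np.asarray(concentrations, float)
    rng = np.random.default_rng(seed)
    rows = []
    for c in concentrations:
        mu = logistic4(np.log10(c), bottom, fmax, np.log10(ec50_um), hill)
        vals = np.full(n_cells, mu)
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, n_cells)
        for cell, v in enumerate(vals):
            rows.append({"conc_um": float(c), "cell": cell, "max_f_over_f0": float(v)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# docking-pose fixtures


def _parse_residue_key(key: str) -> tuple[str, int]:
    """'F1715' or 'PHE1715' -> ('PHE', 1715)."""
    alpha = "".join(ch for ch in key if ch.isalpha())
    num = "".join(ch for ch in key if ch.isdigit())
    if not num:
        raise ValueError(f"residue key {key!r} lacks a residue number")
    if len(alpha) == 1:
        resname = _ONE_TO_THREE.get(alpha.upper())
        if resname is None:
            raise ValueError(f"unknown one-letter residue code in {key!r}")
    elif len(alpha) == 3:
        resname = alpha.upper()
    else:
        raise ValueError(f"residue key {key!r} must use 1- or 3-letter codes")
    return resname, int(num)


def generate_toy_pose_ensemble(
    n_poses: int, contact_plan: dict[str, float], seed: int = 0
) -> PoseEnsemble:
    """Construct a pose ensemble with exactly planned contact fractions.

    Receptor residues (single CA atoms, chain A) are placed 10 A apart on a
    line; pose j's ligand carries one atom 2 A from each residue planned to
    contact in that pose (so the 3.5 A criterion holds for exactly
    ``round(fraction * n_poses)`` poses per residue, and for no others), plus
    a far-away anchor atom so every pose has at least one ligand atom.  The
    separated-line construction makes every plan with fractions in [0, 1]
    geometrically satisfiable; fractions outside [0, 1] are rejected.
    """
    if n_poses < 1:
        raise ValueError("n_poses must be >= 1")
    for key, frac in contact_plan.items():
        if not (0.0 <= frac <= 1.0):
            raise ValueError(f"unsatisfiable plan: fraction for {key!r} is {frac}")
    rng = np.random.default_rng(seed)
    residues = [( *_parse_residue_key(k), k) for k in contact_plan]
    receptor_rows = []
    positions = {}
    for idx, (resname, resseq, _key) in enumerate(residues):
        pos = np.array([10.0 * idx, 0.0, 0.0])
        positions[(resname, resseq)] = pos
        receptor_rows.append(
            {
                "chain": "A", "resseq": resseq, "resname": resname,
                "atom_name": "CA", "element": "C",
                "x": pos[0], "y": pos[1], "z": pos[2],
                "hetero": False, "is_ligand": False,
            }
        )
    receptor = pd.DataFrame(receptor_rows)

    contact_poses = {
        (resname, resseq): set(
            rng.choice(n_poses, size=int(round(contact_plan[key] * n_poses)), replace=False)
        )
        for resname, resseq, key in residues
    }
    poses = []
    for j in range(n_poses):
        rows = [
            {
                "chain": "L", "resseq": 1, "resname": "LIG",
                "atom_name": "C1", "element": "C",
                "x": -50.0, "y": 50.0, "z": 50.0,  # anchor, contacts nothing
                "hetero": True, "is_ligand": True,
            }
        ]
        atom_no = 2
        for (resname, resseq), pose_set in contact_poses.items():
            if j in pose_set:
                pos = positions[(resname, resseq)]
                rows.append(
                    {
                        "chain": "L", "resseq": 1, "resname": "LIG",
                        "atom_name": f"C{atom_no}", "element": "C",
                        "x": pos[0], "y": pos[1] + 2.0, "z": pos[2],
                        "hetero": True, "is_ligand": True,
                    }
                )
                atom_no += 1
        poses.append(pd.DataFrame(rows))
    if len(receptor) == 0:
        # empty plan: keep a dummy far-away residue so distance checks remain valid
        receptor = pd.DataFrame(
            [
                {
                    "chain": "A", "resseq": 1, "resname": "GLY",
                    "atom_name": "CA", "element": "C",
                    "x": 500.0, "y": 500.0, "z": 500.0,
                    "hetero": False, "is_ligand": False,
                }
            ]
        )
    return PoseEnsemble(receptor=receptor, poses=poses)
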