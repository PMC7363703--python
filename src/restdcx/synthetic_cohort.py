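"""Synthetic resting-state cohort generator.

Real resting-state EEG of the kind this pipeline analyses is not publicly
available, so every downstream stage is exercised on a simulated cohort with
known ground truth. Each subject owns a stable sparse MVAR network over
grey-matter parcels: control networks couple predominantly within
resting-state-network (RSN) blocks, while patient networks carry denser and
stronger cross-RSN coupling — the generative analogue of the pathologically
increased network integration the pipeline is designed to detect. Source
activity is simulated by iterating the MVAR recursion with unit-variance
Gaussian innovations, projected to scalp sensors through a spherical forward
model, and degraded with white sensor noise at a configurable SNR.

Innovations are unit-variance with diagonal covariance by design: at ground
truth the information PDC then coincides with the generalized PDC, which
gives the connectivity stage a closed-form normalization check.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import EpochSet
from .exceptions import InvalidSpecError, ShapeError, StabilityError
from .parcellation import load_parcellation, numeric_rsn_labels

_SPAWN_NETWORK = 0
_SPAWN_SIMULATE = 1
_SPAWN_NOISE = 2
_SPAWN_METADATA = 3


@dataclass(frozen=True)
class CohortSpec:
    """Cohort-level simulation parameters.

    ``samples_per_epoch`` counts samples after the 250 Hz down-sampling step;
    scalp data are simulated natively at ``native_fs`` (1000 Hz) so the
    preprocessing stage has real work to do. ``patient_gain`` multiplies
    cross-RSN coupling weights in patient networks; ``extra_edges`` adds new
    long-range (cross-RSN) couplings on top.
    """

    n_controls: int = 16
    n_patients: int = 49
    n_nodes: int = 82
    n_sensors: int = 128
    epochs_per_subject: int = 45
    samples_per_epoch: int = 250
    fs_out: float = 250.0
    native_fs: float = 1000.0
    snr_db: float = 10.0
    patient_gain: float = 1.5
    extra_edges: int = 10
    order: int = 2
    stability_margin: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_controls", "n_patients", "n_nodes", "n_sensors",
                     "epochs_per_subject", "samples_per_epoch"):
            if getattr(self, name) < 1:
                raise InvalidSpecError(f"{name} must be >= 1")
        if not np.isfinite(self.snr_db) and self.snr_db != np.inf:
            raise InvalidSpecError("snr_db must be finite (or +inf for noiseless)")
        if self.patient_gain < 1:
            raise InvalidSpecError("patient_gain must be >= 1")
        if self.extra_edges < 0:
            raise InvalidSpecError("extra_edges must be >= 0")
        if not 0 < self.stability_margin < 1:
            raise InvalidSpecError("stability_margin must be in (0, 1)")

    @property
    def native_samples_per_epoch(self) -> int:
        return int(round(self.samples_per_epoch * self.native_fs / self.fs_out))


@dataclass
class GroundTruthNetwork:
    """Stable MVAR coupling structure of one simulated subject.

    ``coeffs[r][i][j]`` is the influence of node ``j`` at lag ``r+1`` on node
    ``i``. ``rsn_labels`` holds per-node network ids in 1..7.
    """

    order: int
    coeffs: np.ndarray  # (p, n, n)
    rsn_labels: np.ndarray  # (n,), ints in 1..7
    stability_margin: float

    @property
    def n_nodes(self) -> int:
        return self.coeffs.shape[1]

    def spectral_radius(self) -> float:
        return companion_spectral_radius(self.coeffs)

    def is_stable(self) -> bool:
        return self.spectral_radius() < 1.0


@dataclass(frozen=True)
class SensorArray:
    """Unit-sphere sensor montage with an average reference."""

    positions: np.ndarray  # (n_sensors, 3)
    reference: str = "average"

    def __post_init__(self) -> None:
        norms = np.linalg.norm(self.positions, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ShapeError("sensor positions must lie on the unit sphere")


def companion_spectral_radius(coeffs: np.ndarray) -> float:
    """Spectral radius of the companion matrix of a stacked MVAR coefficient set."""
    coeffs = np.asarray(coeffs, dtype=float)
    p, n, _ = coeffs.shape
    companion = np.zeros((n * p, n * p))
    companion[:n, :] = np.concatenate(list(coeffs), axis=1)
    if p > 1:
        companion[n:, :-n] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(companion))))


def _node_rsn_labels(n_nodes: int) -> np.ndarray:
    """Per-node RSN id. The 82-node case uses the bundled parcellation; smaller
    node counts cycle through as many networks as admit >= 2 nodes each."""
    if n_nodes == 82:
        return np.asarray(numeric_rsn_labels(load_parcellation()), dtype=int)
    n_networks = max(1, min(7, n_nodes // 2))
    return np.sort(np.arange(n_nodes) % n_networks) + 1


def _rng(spec: CohortSpec, spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(spawn_key,)))


def make_ground_truth_network(spec: CohortSpec, group: str) -> GroundTruthNetwork:
    """Draw one subject's directed ground-truth network.

    Control networks connect mostly within RSN blocks with weak sparse
    cross-RSN coupling. Patient networks are drawn from the same base
    distribution (identical random stream), then cross-RSN weights are scaled
    by ``patient_gain`` and ``extra_edges`` additional cross-RSN couplings
    are planted. Coefficients are uniformly shrunk, if needed, until the
    companion spectral radius is at most ``1 - stability_margin``.
    """
    if group not in ("control", "patient"):
        raise InvalidSpecError(f"group must be 'control' or 'patient', got {group!r}")
    rng = _rng(spec, _SPAWN_NETWORK)
    n = spec.n_nodes
    p = spec.order
    labels = _node_rsn_labels(n)
    same_rsn = labels[:, None] == labels[None, :]
    off_diag = ~np.eye(n, dtype=bool)

    coeffs = np.zeros((p, n, n))
    # lag-1 self-coupling in [0, 1)
    coeffs[0][np.diag_indices(n)] = rng.uniform(0.25, 0.45, size=n)
    # within-RSN directed edges
    within = same_rsn & off_diag & (rng.random((n, n)) < 0.35)
    signs = rng.choice([-1.0, 1.0], size=(n, n))
    mags = rng.uniform(0.15, 0.35, size=(n, n))
    coeffs[0][within] = (signs * mags)[within]
    # weak baseline cross-RSN edges
    cross_mask = ~same_rsn
    cross = cross_mask & (rng.random((n, n)) < 0.04)
    cross_signs = rng.choice([-1.0, 1.0], size=(n, n))
    cross_mags = rng.uniform(0.05, 0.15, size=(n, n))
    coeffs[0][cross] = (cross_signs * cross_mags)[cross]
    if p > 1:
        # damped second-lag self term gives each node a non-trivial spectrum
        coeffs[1][np.diag_indices(n)] = -0.2 * np.diag(coeffs[0])

    if group == "patient":
        coeffs[0][cross] *= spec.patient_gain
        if spec.extra_edges > 0:
            candidates = np.argwhere(cross_mask & ~cross)
            if len(candidates) < spec.extra_edges:
                raise InvalidSpecError("extra_edges exceeds available cross-RSN pairs")
            idx = rng.choice(len(candidates), size=spec.extra_edges, replace=False)
            w = rng.choice([-1.0, 1.0], size=spec.extra_edges) * rng.uniform(
                0.25, 0.45, size=spec.extra_edges
            )
            rows = candidates[idx]
            coeffs[0][rows[:, 0], rows[:, 1]] = w

    target = 1.0 - spec.stability_margin
    rho = companion_spectral_radius(coeffs)
    for _ in range(200):
        if rho <= target:
            break
        coeffs *= 0.97 * target / rho
        rho = companion_spectral_radius(coeffs)
    if rho > target:  # pragma: no cover - shrink always terminates
        raise StabilityError("could not stabilise generated network")

    return GroundTruthNetwork(
        order=p, coeffs=coeffs, rsn_labels=labels, stability_margin=spec.stability_margin
    )


def ground_truth_weights(network: GroundTruthNetwork) -> np.ndarray:
    """Directed weight matrix implied by the ground truth: entry [j][i] is the
    lag-summed absolute coupling from node j onto node i, zero diagonal.

    Orientation follows the connectivity-matrix convention (row = source)."""
    w = np.sum(np.abs(network.coeffs), axis=0).T.copy()
    np.fill_diagonal(w, 0.0)
    return w


def simulate_source_epochs(
    network: GroundTruthNetwork,
    spec: CohortSpec,
    n_samples: int | None = None,
    burn_in: int = 500,
) -> np.ndarray:
    """Simulate source activity: returns (n_nodes, n_samples, n_epochs).

    Each epoch iterates the MVAR recursion from zero initial conditions with
    unit-variance Gaussian innovations; the first ``burn_in`` samples are
    discarded so the retained segment is (approximately) stationary.
    """
    if not network.is_stable():
        raise StabilityError("network is unstable; refusing to simulate")
    rng = _rng(spec, _SPAWN_SIMULATE)
    n = network.n_nodes
    p = network.order
    n_samples = spec.native_samples_per_epoch if n_samples is None else int(n_samples)
    n_epochs = spec.epochs_per_subject
    total = burn_in + n_samples

    out = np.empty((n, n_samples, n_epochs))
    # history[r] holds x_{t-1-r}; epochs run in parallel as columns
    history = np.zeros((p, n, n_epochs))
    eps = rng.standard_normal((total, n, n_epochs))
    for t in range(total):
        x = eps[t]
        for r in range(p):
            x = x + network.coeffs[r] @ history[r]
        if t >= burn_in:
            out[:, t - burn_in, :] = x
        history = np.roll(history, 1, axis=0)
        history[0] = x
    if not np.all(np.isfinite(out)):
        raise StabilityError("simulation diverged")
    return out


def make_sensor_array(n_sensors: int = 128) -> SensorArray:
    """Deterministic EEG-like montage: a spiral of points on the upper
    spherical cap (z >= -0.25), mimicking scalp coverage."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = np.linspace(-0.25, 0.995, n_sensors)
    theta = golden * np.arange(n_sensors)
    r = np.sqrt(1.0 - z**2)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    pos /= np.linalg.norm(pos, axis=1, keepdims=True)
    return SensorArray(positions=pos)


def make_roi_centroids(n_nodes: int, radius: float = 0.7) -> np.ndarray:
    """Deterministic parcel-centroid positions on a shell inside the head sphere."""
    golden = np.pi * (3.0 - np.sqrt(5.0))
    z = np.linspace(-0.85, 0.85, n_nodes)
    theta = golden * np.arange(n_nodes)
    r = np.sqrt(1.0 - z**2)
    pos = np.column_stack([r * np.cos(theta), r * np.sin(theta), z])
    return radius * pos


def project_to_scalp(
    source: np.ndarray,
    gain: np.ndarray,
    snr_db: float,
    seed: int | np.random.Generator,
    fs: float,
    return_parts: bool = False,
):
    """Project source epochs to scalp sensors and add white noise at snr_db.

    ``source`` is (n_nodes, samples, epochs); ``gain`` is (sensors, nodes),
    one fixed-orientation equivalent dipole per parcel centroid. Noise power
    is set from the mean signal power over channels and samples so that
    10*log10(P_signal / P_noise) = snr_db; ``snr_db = inf`` disables noise.
    The average reference is applied after noise addition.
    """
    source = np.asarray(source, dtype=float)
    gain = np.asarray(gain, dtype=float)
    if source.ndim != 3:
        raise ShapeError("source must be 3-D (nodes x samples x epochs)")
    if gain.ndim != 2 or gain.shape[1] != source.shape[0]:
        raise ShapeError(
            f"lead-field columns ({gain.shape[1]}) must match source nodes ({source.shape[0]})"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    # (epochs, sensors, samples)
    clean = np.einsum("cn,nse->ecs", gain, source)
    if np.isinf(snr_db):
        noise = np.zeros_like(clean)
    else:
        p_signal = float(np.mean(clean**2))
        # zero signal has no defined SNR; fall back to unit-variance noise
        p_noise = p_signal / (10.0 ** (snr_db / 10.0)) if p_signal > 0 else 1.0
        noise = rng.normal(scale=np.sqrt(p_noise), size=clean.shape)
    data = clean + noise
    data = data - data.mean(axis=1, keepdims=True)  # average reference
    epochs = EpochSet(data=data, fs=fs)
    if return_parts:
        ref = lambda x: x - x.mean(axis=1, keepdims=True)  # noqa: E731
        return epochs, ref(clean), ref(noise)
    return epochs


_LOBES = ("temporal", "extratemporal")
_ILAE_PROBS = (0.40, 0.20, 0.20, 0.10, 0.10)


def _draw_metadata(rng: np.random.Generator, subject_id: str, group: str) -> dict:
    """Synthetic clinical covariates. Drawn independently of the network gain,
    so clinical correlations are null by construction."""
    if group == "control":
        return {
            "subject_id": subject_id, "group": group, "lobe": "na",
            "lesional": "na", "side": "na", "ilae": "",
            "onset_age": "", "duration": "",
        }
    lobe = _LOBES[0] if rng.random() < 37 / 49 else _LOBES[1]
    lesional = "yes" if rng.random() < 35 / 49 else "no"
    side = "L" if rng.random() < 0.5 else "R"
    ilae = int(rng.choice(np.arange(1, 6), p=_ILAE_PROBS))
    onset = int(rng.integers(5, 41))
    duration = int(rng.integers(1, 31))
    return {
        "subject_id": subject_id, "group": group, "lobe": lobe,
        "lesional": lesional, "side": side, "ilae": ilae,
        "onset_age": onset, "duration": duration,
    }


def subject_specs(spec: CohortSpec) -> list[tuple[str, str, CohortSpec]]:
    """Per-subject (subject_id, group, spec-with-private-seed) triples.

    Each subject gets an independent seed derived from the cohort seed, so
    subjects are i.i.d. draws within their group."""
    n_total = spec.n_controls + spec.n_patients
    children = np.random.SeedSequence(spec.seed).spawn(n_total)
    out = []
    for i, child in enumerate(children):
        group = "control" if i < spec.n_controls else "patient"
        sub_seed = int(child.generate_state(1, dtype=np.uint32)[0] % (2**31))
        out.append(
            (f"sub-{i:03d}", group, dataclasses.replace(spec, seed=sub_seed))
        )
    return out


def generate_cohort(spec: CohortSpec, out_dir) -> pd.DataFrame:
    """Write a full synthetic cohort bundle and return the metadata table.

    Per subject: a scalp EpochSet (native sampling rate) in HDF5. Cohort
    level: ``metadata.csv``, a ground-truth archive with every subject's
    coefficient stack, and ``cohort.json`` provenance.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sensors = make_sensor_array(spec.n_sensors)
    from .source_reconstruction import build_spherical_lead_field

    centroids = make_roi_centroids(spec.n_nodes)
    lf = build_spherical_lead_field(sensors, centroids, roi_index=np.arange(spec.n_nodes) + 1)

    meta_rows = []
    gt_path = out_dir / "ground_truth.h5"
    with h5py.File(gt_path, "w") as gt:
        for subject_id, group, sub_spec in subject_specs(spec):
            network = make_ground_truth_network(sub_spec, group)
            source = simulate_source_epochs(network, sub_spec)
            noise_rng = _rng(sub_spec, _SPAWN_NOISE)
            epochs = project_to_scalp(
                source, lf.gain, sub_spec.snr_db, noise_rng, fs=sub_spec.native_fs
            )
            epochs.save(out_dir / f"{subject_id}_epochs.h5")
            grp = gt.create_group(subject_id)
            grp.create_dataset("coeffs", data=network.coeffs)
            grp.create_dataset("rsn_labels", data=network.rsn_labels)
            grp.attrs["group"] = group
            grp.attrs["seed"] = sub_spec.seed
            meta_rng = _rng(sub_spec, _SPAWN_METADATA)
            meta_rows.append(_draw_metadata(meta_rng, subject_id, group))

    metadata = pd.DataFrame(
        meta_rows,
        columns=["subject_id", "group", "lobe", "lesional", "side", "ilae",
                 "onset_age", "duration"],
    )
    metadata.to_csv(out_dir / "metadata.csv", index=False)
    with open(out_dir / "cohort.json", "w") as fh:
        json.dump(dataclasses.asdict(spec), fh, indent=2, sort_keys=True)
    return metadata
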