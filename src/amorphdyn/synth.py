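"""Synthetic data with known ground truth for every pipeline stage.

Three generators, all bit-reproducible under a fixed seed and all returning
their planted truth as a JSON-ready manifest next to the data:

* :func:`gen_relaxation_map` — tau_alpha(T, p) sampled from a planted
  modified-Avramov surface with Gaussian noise in decades of log10(tau);
* :func:`gen_spectra` — loss spectra whose structural HN process peaks at
  the planted tau_alpha (plus an Arrhenius secondary process and a
  dc-conductivity wing), with multiplicative lognormal noise;
* :func:`gen_configuration` — periodic boxes containing planted H-bond
  motifs (monomers, linear/cyclic dimers and trimers, zigzag chains) and
  planted parallel/antiparallel ring-stacking pairs.

Molecules are a simplified rigid template — a fluorinated six-ring plus a
carboxylic acid head — because the downstream analyses consume the H-bond
graph and the stacking geometry, not chemistry.  Chirality is a label.
Motifs are built so every planted H-bond has d(O...O) = 2.75 A at a
180-degree O-H...O angle, intra-motif geometry stays clear of the default
stacking windows, and motifs are separated by a clearance that excludes
both accidental H-bonds and accidental stacking classifications.

The default surface parameters encode the study conditions of a fragile
glass-forming drug: tau_inf = 1e-14 s, T_r near 263 K, Pi = 1 GPa and
exponents giving a fragility m near 80 and dTg/dp near 0.25 K/MPa.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spectra import HNProcess, LossSpectrum, SpectrumModel, evaluate_model, \
    hn_time_from_peak
from .structures import Atom, Configuration, Molecule, minimum_image_vector
from .surface import AvramovParams, RelaxationMap

R_GAS = 8.31446

MAX_PLACEMENT_ATTEMPTS = 100_000
MIN_SEPARATION_DEFAULT = 7.5  # A: clears the H-bond cutoff and both stacking windows


# ---------------------------------------------------------------------------
# planted relaxation surfaces
# ---------------------------------------------------------------------------

def default_avramov_truth(sample: str = "enantiomer") -> AvramovParams:
    """Planted tau(T, p) surfaces for the two demo systems.

    The enantiomer-like surface is more fragile and more pressure sensitive
    (higher activation volume) than the racemate-like one; both share the
    pressure scale Pi = 1 GPa and tau_inf = 1e-14 s.
    """
    if sample in ("enantiomer", "S", "R"):
        return AvramovParams(log10_tau_inf=-14.0, T_r_K=263.4, Pi_MPa=1000.0,
                             alpha0=5.09, beta_exp=4.77)
    if sample in ("racemate", "RS"):
        return AvramovParams(log10_tau_inf=-14.0, T_r_K=261.9, Pi_MPa=1000.0,
                             alpha0=4.44, beta_exp=4.20)
    raise ValueError(f"unknown sample preset {sample!r}")


def temperature_for_tau(params: AvramovParams, log10_tau_target: float,
                        p_MPa: float) -> float:
    """Invert the surface: the T at which log10 tau reaches the target."""
    span = params.log10_tau_g - params.log10_tau_inf
    q = (log10_tau_target - params.log10_tau_inf) / span
    if q <= 0:
        raise ValueError("target below tau_inf")
    scale = (1.0 + p_MPa / params.Pi_MPa) ** (params.beta_exp / params.alpha0)
    return float(params.T_r_K * scale * q ** (-1.0 / params.alpha0))


@dataclass
class SpectraScenario:
    """Planted truth + measurement grid for synthetic dielectric spectra."""

    avramov_truth: AvramovParams
    temperature_K: np.ndarray
    pressure_MPa: np.ndarray
    f_grid_hz: np.ndarray = field(
        default_factory=lambda: np.logspace(-2.0, 6.0, 321))  # 40 pts/decade
    alpha_shape: float = 0.85
    beta_shape: float = 0.60
    delta_eps: float = 5.0
    sigma_dc_at_1s: float = 2e-12  # S/m when tau_alpha = 1 s; scales as 1/tau
    include_secondary: bool = True
    sec_alpha: float = 0.55
    sec_beta: float = 1.0
    sec_delta_eps: float = 0.4
    # secondary peak time tied to the structural one (isochronal alpha-beta
    # superposition): log10 tau_beta = log10(sec_tau_at_1s) + c*log10 tau_alpha
    sec_tau_at_1s_s: float = 1e-5
    sec_coupling: float = 0.5
    noise_relative: float = 0.01
    noise_decades: float = 0.05
    seed: int = 0
    sample_id: str = "S"

    def __post_init__(self) -> None:
        self.temperature_K = np.atleast_1d(np.asarray(self.temperature_K, float))
        self.pressure_MPa = np.atleast_1d(np.asarray(self.pressure_MPa, float))
        if self.temperature_K.shape != self.pressure_MPa.shape:
            raise ValueError("temperature and pressure condition lists must match")
        self.f_grid_hz = np.asarray(self.f_grid_hz, float)
        if self.noise_relative < 0 or self.noise_decades < 0:
            raise ValueError("noise levels must be nonnegative")

    @classmethod
    def from_isobars(cls, avramov_truth: AvramovParams,
                     pressures_MPa: Sequence[float],
                     log10_tau_targets: Sequence[float],
                     **kwargs) -> "SpectraScenario":
        """Conditions placed at fixed log10(tau) targets along each isobar,
        mirroring how isobaric sweeps track the alpha peak through the
        experimental frequency window."""
        T, p = [], []
        for pres in pressures_MPa:
            for y in log10_tau_targets:
                T.append(temperature_for_tau(avramov_truth, y, pres))
                p.append(pres)
        return cls(avramov_truth=avramov_truth, temperature_K=np.array(T),
                   pressure_MPa=np.array(p), **kwargs)


def gen_relaxation_map(scenario: SpectraScenario):
    """Sample tau_alpha(T, p) from the planted surface (noise in decades)."""
    rng = np.random.default_rng(scenario.seed)
    log_tau = np.asarray(scenario.avramov_truth.log10_tau(
        scenario.temperature_K, scenario.pressure_MPa), float)
    noisy = log_tau + rng.normal(0.0, scenario.noise_decades, size=log_tau.shape) \
        if scenario.noise_decades > 0 else log_tau
    rmap = RelaxationMap(
        temperature_K=scenario.temperature_K,
        pressure_MPa=scenario.pressure_MPa,
        tau_alpha_s=10.0 ** noisy,
        sigma_log10tau=(np.full_like(log_tau, scenario.noise_decades)
                        if scenario.noise_decades > 0 else None),
        sample_id=scenario.sample_id,
    )
    manifest = {
        "seed": scenario.seed,
        "sample_id": scenario.sample_id,
        "avramov_truth": {
            "log10_tau_inf": scenario.avramov_truth.log10_tau_inf,
            "T_r_K": scenario.avramov_truth.T_r_K,
            "Pi_MPa": scenario.avramov_truth.Pi_MPa,
            "alpha0": scenario.avramov_truth.alpha0,
            "beta_exp": scenario.avramov_truth.beta_exp,
        },
        "noise_decades": scenario.noise_decades,
        "log10_tau_true": log_tau.tolist(),
    }
    return rmap, manifest


def gen_spectra(scenario: SpectraScenario):
    """Synthesise one loss spectrum per (T, p) condition.

    The structural HN time is back-computed from the planted tau_alpha so
    the loss peak sits exactly at 1/(2 pi tau_alpha); the secondary process
    follows an Arrhenius law; sigma_dc tracks 1/tau_alpha.
    """
    rng = np.random.default_rng(scenario.seed)
    spectra, conditions = [], []
    f = scenario.f_grid_hz
    for T, p in zip(scenario.temperature_K, scenario.pressure_MPa):
        log_tau = float(scenario.avramov_truth.log10_tau(T, p))
        tau_alpha = 10.0 ** log_tau
        tau_hn = hn_time_from_peak(tau_alpha, scenario.alpha_shape,
                                   scenario.beta_shape)
        procs = [HNProcess(scenario.delta_eps, tau_hn, scenario.alpha_shape,
                           scenario.beta_shape, label="structural")]
        truth = {
            "temperature_K": float(T), "pressure_MPa": float(p),
            "tau_alpha_s": tau_alpha, "tau_hn_s": tau_hn,
            "delta_eps": scenario.delta_eps,
            "alpha_shape": scenario.alpha_shape,
            "beta_shape": scenario.beta_shape,
        }
        if scenario.include_secondary:
            tau_beta_peak = scenario.sec_tau_at_1s_s \
                * tau_alpha ** scenario.sec_coupling
            tau_beta_hn = hn_time_from_peak(tau_beta_peak, scenario.sec_alpha,
                                            scenario.sec_beta)
            procs.append(HNProcess(scenario.sec_delta_eps, tau_beta_hn,
                                   scenario.sec_alpha, scenario.sec_beta,
                                   label="secondary"))
            truth.update(sec_tau_alpha_s=float(tau_beta_peak),
                         sec_tau_hn_s=float(tau_beta_hn),
                         sec_delta_eps=scenario.sec_delta_eps,
                         sec_alpha=scenario.sec_alpha,
                         sec_beta=scenario.sec_beta)
        sigma_dc = scenario.sigma_dc_at_1s / tau_alpha
        truth["sigma_dc"] = sigma_dc
        model = SpectrumModel(processes=tuple(procs), sigma_dc=sigma_dc)
        loss = evaluate_model(model, f)
        if scenario.noise_relative > 0:
            loss = loss * np.exp(rng.normal(0.0, scenario.noise_relative,
                                            size=loss.shape))
        spectra.append(LossSpectrum(frequency_hz=f.copy(), loss=loss,
                                    temperature_K=float(T),
                                    pressure_MPa=float(p),
                                    sample_id=scenario.sample_id))
        conditions.append(truth)
    manifest = {
        "seed": scenario.seed,
        "sample_id": scenario.sample_id,
        "noise_relative": scenario.noise_relative,
        "conditions": conditions,
    }
    return spectra, manifest


# ---------------------------------------------------------------------------
# rigid molecular template
# ---------------------------------------------------------------------------

# element, role, xyz (A): fluorinated six-ring + carboxylic acid head.
# O-H points along -x; the carbonyl acceptor sits 2.30 A from the hydroxyl O.
_TEMPLATE = (
    ("C", "C_ring_F", (1.39, 0.0, 0.0)),
    ("C", "C_ring", (0.695, 1.2038, 0.0)),
    ("C", "C_ring", (-0.695, 1.2038, 0.0)),
    ("C", "C_ring", (-1.39, 0.0, 0.0)),
    ("C", "C_ring", (-0.695, -1.2038, 0.0)),
    ("C", "C_ring", (0.695, -1.2038, 0.0)),
    ("F", "F", (2.74, 0.0, 0.0)),
    ("C", "other", (-2.89, 0.0, 0.0)),
    ("O", "O_carbonyl", (-3.50, 1.15, 0.0)),
    ("O", "O_hydroxyl", (-3.50, -1.15, 0.0)),
    ("H", "H_hydroxyl", (-4.47, -1.15, 0.0)),
)
_T_XYZ = np.array([a[2] for a in _TEMPLATE])
_I_OH = 9   # O_hydroxyl row
_I_HH = 10  # H_hydroxyl row
_I_OC = 8   # O_carbonyl row
D_OO = 2.75  # planted O...O bond length, A


def _frame_rotation(e_hat: np.ndarray, p_hat: np.ndarray) -> np.ndarray:
    """Rotation mapping the template O->H axis onto e_hat and the
    O_hydroxyl->O_carbonyl perpendicular onto p_hat (always proper)."""
    c1 = -np.asarray(e_hat, float)  # template x axis maps to -e_hat
    c2 = np.asarray(p_hat, float)
    c3 = np.cross(c1, c2)
    return np.column_stack([c1, c2, c3])


def _place(Rm: np.ndarray, origin_target: np.ndarray,
           origin_template: np.ndarray) -> np.ndarray:
    """Template coordinates under x -> R (x - origin_template) + target."""
    return (_T_XYZ - origin_template) @ Rm.T + origin_target


CHAIN_TURN_DEG = 40.0


def _chain_motif(k: int) -> tuple[np.ndarray, list[tuple[int, int]], str]:
    """Zigzag H-bonded chain of k molecules (alternating 40-degree turns).

    Each molecule donates its hydroxyl H along the next chain edge.  The
    turn angle keeps every non-bonded O...O contact above the 3.5 A cutoff
    and every same-parity F...C_ring contact (which has theta = 0) outside
    the antiparallel window: at 40 degrees the closest offset-4 contact
    sits at 7.4 A, the offset-2 one at 3.3 A.
    """
    if k < 2:
        raise ValueError("chains need k >= 2")
    c = np.cos(np.radians(CHAIN_TURN_DEG))
    s = np.sin(np.radians(CHAIN_TURN_DEG))
    coords = []
    v = np.zeros(3)
    for i in range(k):
        sgn = 1.0 if i % 2 == 0 else -1.0
        e_hat = np.array([c, s * sgn, 0.0])
        p_hat = np.array([s, -c * sgn, 0.0])
        coords.append(_place(_frame_rotation(e_hat, p_hat), v, _T_XYZ[_I_OH]))
        v = v + D_OO * e_hat
    bonds = [(i, i + 1) for i in range(k - 1)]
    label = {2: "linear_dimer", 3: "linear_trimer"}.get(k, "chain_n")
    return np.array(coords), bonds, label


def _cyclic_dimer_motif() -> tuple[np.ndarray, list[tuple[int, int]], str]:
    """Carboxylic-acid-style dimer: two molecules related by a 180-degree
    rotation, each donating to the partner's carbonyl oxygen."""
    a = _T_XYZ.copy()
    rot = np.diag([-1.0, -1.0, 1.0])
    b = a @ rot.T + np.array([-2.0 * 3.50 - D_OO, 0.0, 0.0])
    return np.array([a, b]), [(0, 1), (1, 0)], "cyclic_dimer"


def _cyclic_trimer_motif() -> tuple[np.ndarray, list[tuple[int, int]], str]:
    """Three molecules donating around an equilateral O...O triangle
    (hydroxyl oxygens accept), bodies radiating outward in-plane."""
    rho = D_OO / np.sqrt(3.0)
    verts = [rho * np.array([np.cos(2 * np.pi * i / 3),
                             np.sin(2 * np.pi * i / 3), 0.0]) for i in range(3)]
    coords = []
    for i in range(3):
        v, w = verts[i], verts[(i + 1) % 3]
        e_hat = (w - v) / np.linalg.norm(w - v)
        p_hat = np.array([-e_hat[1], e_hat[0], 0.0])
        if np.dot(p_hat, v) < 0:  # point the molecule body outward
            p_hat = -p_hat
        coords.append(_place(_frame_rotation(e_hat, p_hat), v, _T_XYZ[_I_OH]))
    return np.array(coords), [(0, 1), (1, 2), (2, 0)], "cyclic_trimer"


def _stacking_pair_motif(kind: str) -> tuple[np.ndarray, list, str]:
    """Two molecules with no H-bond, planted at the characteristic F...C_ring
    stacking geometry: (4 A, 180 deg) parallel or (6 A, 0 deg) antiparallel."""
    a = _T_XYZ.copy()
    if kind == "parallel":
        rot = np.diag([-1.0, -1.0, 1.0])
        b = a @ rot.T + np.array([4.13, 0.0, 4.0])  # r = 4.0 A, theta = 180
    elif kind == "antiparallel":
        h = np.sqrt(6.0 ** 2 - 1.35 ** 2)
        b = a + np.array([0.0, 0.0, h])  # r = 6.0 A, theta = 0
    else:
        raise ValueError(f"unknown stacking kind {kind!r}")
    return np.array([a, b]), [], f"stacking_{kind}"


def _monomer_motif() -> tuple[np.ndarray, list, str]:
    return _T_XYZ[None, :, :].copy(), [], "monomer"


# ---------------------------------------------------------------------------
# configuration scenario and generator
# ---------------------------------------------------------------------------

@dataclass
class ConfigScenario:
    """Planted composition of one periodic box."""

    box_angstrom: tuple[float, float, float] = (80.0, 80.0, 80.0)
    counts: dict = field(default_factory=dict)
    # e.g. {"monomer": 5, "linear_dimer": 3, "cyclic_dimer": 1,
    #       "linear_trimer": 2, "cyclic_trimer": 1, "chain_5": 2}
    stacking_pairs: dict = field(default_factory=dict)  # {"parallel": n, ...}
    chirality_s_fraction: float = 1.0
    min_separation_angstrom: float = MIN_SEPARATION_DEFAULT
    seed: int = 0
    sample_id: str = "S"

    def motif_list(self) -> list[str]:
        order = ["monomer", "linear_dimer", "cyclic_dimer", "linear_trimer",
                 "cyclic_trimer"]
        names = []
        for key in order:
            names.extend([key] * int(self.counts.get(key, 0)))
        for key in sorted(self.counts):
            if key.startswith("chain_"):
                names.extend([key] * int(self.counts[key]))
            elif key not in order:
                raise ValueError(f"unknown motif {key!r}")
        for kind in ("parallel", "antiparallel"):
            names.extend([f"stacking_{kind}"]
                         * int(self.stacking_pairs.get(kind, 0)))
        return names


def _build_motif(name: str):
    if name == "monomer":
        return _monomer_motif()
    if name == "linear_dimer":
        return _chain_motif(2)
    if name == "linear_trimer":
        return _chain_motif(3)
    if name == "cyclic_dimer":
        return _cyclic_dimer_motif()
    if name == "cyclic_trimer":
        return _cyclic_trimer_motif()
    if name.startswith("chain_"):
        return _chain_motif(int(name.split("_")[1]))
    if name.startswith("stacking_"):
        return _stacking_pair_motif(name.split("_", 1)[1])
    raise ValueError(f"unknown motif {name!r}")


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform proper rotation from a normalised random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def gen_configuration(scenario: ConfigScenario):
    """Place planted motifs in a periodic box with guaranteed clearance.

    Motifs are rigidly rotated (uniform) and translated by rejection
    sampling until bounding spheres are separated by at least
    ``min_separation_angstrom`` under the minimum-image convention, so no
    inter-motif atom pair can form an H-bond or fall into a stacking
    window.  Raises after ``MAX_PLACEMENT_ATTEMPTS`` rejected trials.
    """
    rng = np.random.default_rng(scenario.seed)
    box = np.asarray(scenario.box_angstrom, float)
    clearance = scenario.min_separation_angstrom

    placed_centers: list[np.ndarray] = []
    placed_radii: list[float] = []
    molecules: list[Molecule] = []
    expected_bonds: list[tuple[int, int]] = []
    expected_clusters: list[dict] = []
    expected_stacking = {"parallel": 0, "antiparallel": 0}
    stacking_chirality: list[str] = []

    mol_id = 0
    for name in scenario.motif_list():
        coords, bonds, label = _build_motif(name)
        flat = coords.reshape(-1, 3)
        centroid = flat.mean(axis=0)
        radius = float(np.linalg.norm(flat - centroid, axis=1).max())
        if 2.0 * radius + clearance > box.min():
            raise ValueError(f"motif {name} does not fit in the box")

        for attempt in range(MAX_PLACEMENT_ATTEMPTS + 1):
            if attempt == MAX_PLACEMENT_ATTEMPTS:
                raise RuntimeError(
                    f"could not place motif {name}: box too crowded")
            Q = _random_rotation(rng)
            center = rng.uniform(0.0, box)
            ok = True
            for c_old, r_old in zip(placed_centers, placed_radii):
                d = np.linalg.norm(minimum_image_vector(center - c_old, box))
                if d < radius + r_old + clearance:
                    ok = False
                    break
            if ok:
                break
        placed_centers.append(center)
        placed_radii.append(radius)

        new_ids = []
        chirs = []
        for m in range(coords.shape[0]):
            xyz = (coords[m] - centroid) @ Q.T + center
            chir = "S" if rng.random() < scenario.chirality_s_fraction else "R"
            atoms = [Atom(element=el, role=role, xyz=xyz[i])
                     for i, (el, role, _) in enumerate(_TEMPLATE)]
            molecules.append(Molecule(molecule_id=mol_id, chirality=chir,
                                      atoms=atoms))
            new_ids.append(mol_id)
            chirs.append(chir)
            mol_id += 1

        for a, b in bonds:
            expected_bonds.append((new_ids[a], new_ids[b]))
        if label.startswith("stacking_"):
            kind = label.split("_", 1)[1]
            expected_stacking[kind] += 1
            stacking_chirality.append("-".join(sorted(chirs)))
        elif label != "monomer":
            expected_clusters.append({"members": new_ids, "size": len(new_ids),
                                      "topology": label})

    config = Configuration(box_angstrom=box, molecules=molecules)

    hist: dict[int, int] = {}
    for cl in expected_clusters:
        hist[cl["size"]] = hist.get(cl["size"], 0) + 1
    n_clusters = len(expected_clusters)
    n_low = sum(1 for cl in expected_clusters if 2 <= cl["size"] <= 4)
    dimers = [cl for cl in expected_clusters if cl["size"] == 2]
    trimers = [cl for cl in expected_clusters if cl["size"] == 3]
    manifest = {
        "seed": scenario.seed,
        "sample_id": scenario.sample_id,
        "n_molecules": len(molecules),
        "counts": dict(scenario.counts),
        "stacking_pairs": dict(scenario.stacking_pairs),
        "min_separation_angstrom": clearance,
        "expected": {
            "bonds": expected_bonds,
            "n_monomers": (len(molecules)
                           - sum(cl["size"] for cl in expected_clusters)),
            "histogram": {str(k): v for k, v in sorted(hist.items())},
            "n_clusters": n_clusters,
            "low_fraction": (n_low / n_clusters) if n_clusters else None,
            "cyclic_dimer_share_of_dimers": (
                sum(1 for c in dimers if c["topology"] == "cyclic_dimer")
                / len(dimers)) if dimers else None,
            "cyclic_trimer_share_of_trimers": (
                sum(1 for c in trimers if c["topology"] == "cyclic_trimer")
                / len(trimers)) if trimers else None,
            "clusters": expected_clusters,
            "stacking": expected_stacking,
            "stacking_chirality_pairs": stacking_chirality,
        },
    }
    return config, manifest


def gen_ideal_gas_frames(n_molecules: int, box_angstrom: float,
                         n_frames: int, seed: int = 0) -> list[Configuration]:
    """Uncorrelated frames of randomly placed, randomly oriented molecules
    (the analytic reference for RDF x ADF normalisation)."""
    rng = np.random.default_rng(seed)
    box = np.array([box_angstrom] * 3, float)
    frames = []
    for _ in range(n_frames):
        mols = []
        for i in range(n_molecules):
            Q = _random_rotation(rng)
            t = rng.uniform(0.0, box)
            xyz = _T_XYZ @ Q.T + t
            atoms = [Atom(element=el, role=role, xyz=xyz[j])
                     for j, (el, role, _) in enumerate(_TEMPLATE)]
            mols.append(Molecule(molecule_id=i, chirality="S", atoms=atoms))
        frames.append(Configuration(box_angstrom=box, molecules=mols))
    return frames


# ---------------------------------------------------------------------------
# demo presets
# ---------------------------------------------------------------------------

def preset_config_scenario(name: str, seed: int = 0) -> ConfigScenario:
    """Demonstration compositions mirroring the qualitative contrast between
    a pure enantiomer (more small clusters, parallel-only stacking) and a
    racemate (more long chains, mixed stacking)."""
    if name in ("enantiomer-like", "enantiomer", "S"):
        return ConfigScenario(
            box_angstrom=(110.0, 110.0, 110.0),
            counts={"monomer": 10, "linear_dimer": 7, "cyclic_dimer": 1,
                    "linear_trimer": 10, "cyclic_trimer": 1, "chain_4": 6,
                    "chain_5": 10, "chain_6": 9},
            stacking_pairs={"parallel": 6, "antiparallel": 0},
            chirality_s_fraction=1.0, seed=seed, sample_id="S",
        )
    if name in ("racemate-like", "racemate", "RS"):
        return ConfigScenario(
            box_angstrom=(125.0, 125.0, 125.0),
            counts={"monomer": 10, "linear_dimer": 10, "cyclic_dimer": 1,
                    "linear_trimer": 9, "cyclic_trimer": 2, "chain_4": 4,
                    "chain_5": 17, "chain_6": 16},
            stacking_pairs={"parallel": 5, "antiparallel": 4},
            chirality_s_fraction=0.5, seed=seed, sample_id="RS",
        )
    raise ValueError(f"unknown preset {name!r}")


def preset_spectra_scenario(name: str, seed: int = 0,
                            pressures_MPa: Sequence[float] = (0.1, 100.0, 200.0),
                            log10_tau_targets: Sequence[float] = tuple(
                                np.round(np.linspace(2.0, -3.5, 12), 3)),
                            **kwargs) -> SpectraScenario:
    if name in ("enantiomer-like", "enantiomer", "S"):
        truth, sid = default_avramov_truth("enantiomer"), "S"
    elif name in ("racemate-like", "racemate", "RS"):
        truth, sid = default_avramov_truth("racemate"), "RS"
    else:
        raise ValueError(f"unknown preset {name!r}")
    # the low-frequency limit reaches 1e-4 Hz so the 100 s isochrone is
    # measured rather than extrapolated
    kwargs.setdefault("f_grid_hz", np.logspace(-4.0, 6.0, 401))
    return SpectraScenario.from_isobars(truth, pressures_MPa, log10_tau_targets,
                                        seed=seed, sample_id=sid, **kwargs)
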