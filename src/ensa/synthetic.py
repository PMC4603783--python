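"""Synthetic ensembles with known ground truth.

Every input the analysis pipeline consumes can be generated here at desk
scale with a planted, returned truth: backbone conformations built from
dihedrals by NeRF chain extension, two-population (compact fold vs
extended strand) ensembles with a guaranteed hydrophobic-SASA gap,
archetype contact fingerprints with bit-flip noise, two-state Markov
switching trajectories, and simulated J-coupling tables.

The compact/extended populations are deliberate abstractions.  The
compact template is an N-terminal β-hairpin followed by an α-helix: the
helix keeps hydrophobic solvent exposure low and insensitive to dihedral
jitter, while the hairpin contributes long-range main-chain contacts, so
the planted states are separable both on the SASA axis and in contact
space.  The extended template is a straight β-strand.  Neither models
the side-chain packing of a real hydrophobic collapse — the contract the
pipeline needs is a controllable exposure gap and contact-pattern
difference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import (AA_THREE_LETTER, ABETA42_SEQUENCE, ATOMIC_MASSES,
                   AtomRecord, DEFAULT_HYDROPHOBIC_SET, Ensemble, Frame,
                   ObservableTable, Topology, VDW_RADII)
from .nmr import KarplusCoefficients, karplus_j
from .sasa import SasaParams, hydrophobic_sasa

__all__ = ["GeneratorSpec", "HELIX_TEMPLATE", "STRAND_TEMPLATE",
           "compact_fold_angles",
           "build_backbone", "build_hairpin", "backbone_topology",
           "generate_two_state_ensemble", "generate_archetype_fingerprints",
           "generate_markov_trajectories", "simulate_j_table",
           "random_phi_distributions"]

#: (φ, ψ) of an ideal α-helix.
HELIX_TEMPLATE = (-57.0, -47.0)
#: (φ, ψ) of an extended β-strand — the extended-state template.
STRAND_TEMPLATE = (-139.0, 135.0)

_SHEET_STRAND = (-125.0, 130.0)
_SHEET_TURN = ((57.0, -126.0), (-91.0, 5.0))


def compact_fold_angles(n_residues: int, hairpin_strand: int = 6) -> np.ndarray:
    """Per-residue (φ, ψ) of the default compact-state template.

    An N-terminal antiparallel β-hairpin (``hairpin_strand`` residues per
    strand around a two-residue type II′-like turn) followed by an
    α-helix.  The helix keeps the chain compact — and the hydrophobic
    solvent exposure low and jitter-robust — while the hairpin gives the
    compact state long-range main-chain contacts, so the two planted
    states differ in contact space as well as in SASA.
    """
    ns = min(hairpin_strand, max((n_residues - 2) // 2, 1))
    n_helix = n_residues - 2 * ns - 2
    if n_helix < 0:
        raise ValueError("chain too short for the compact fold template")
    angles = ([_SHEET_STRAND] * ns + list(_SHEET_TURN) + [_SHEET_STRAND] * ns
              + [HELIX_TEMPLATE] * n_helix)
    return np.asarray(angles, dtype=float)


def _resolve_template(template, n_residues: int) -> np.ndarray:
    """Accept a single (φ, ψ) pair or per-residue angles; return (n, 2)."""
    arr = np.asarray(template, dtype=float)
    if arr.shape == (2,):
        return np.tile(arr, (n_residues, 1))
    if arr.shape == (n_residues, 2):
        return arr
    raise ValueError(
        f"template must be a (phi, psi) pair or an ({n_residues}, 2) "
        f"angle array, got shape {arr.shape}"
    )

# ideal backbone internal coordinates (Å / degrees)
_B_N_CA = 1.458
_B_CA_C = 1.525
_B_C_N = 1.329
_B_C_O = 1.231
_B_CA_CB = 1.530
_A_N_CA_C = 111.2
_A_CA_C_N = 116.2
_A_C_N_CA = 121.7
_A_CA_C_O = 120.8
_A_N_CA_CB = 110.6
_OMEGA = 180.0


@dataclass(frozen=True)
class GeneratorSpec:
    """Conditions of a synthetic two-state study.

    The defaults emulate the analysed system: a 42-residue chain, a
    70/30 compact/extended mixture, modest dihedral jitter, and a
    persistent two-state Markov chain (2% switching probability per
    saved frame, i.e. mean dwell ≈ 5 ns at a 100 ps saving interval).
    """

    n_residues: int = 42
    sequence: str | None = None           # one-letter; default: amyloid-beta
    compact_template: tuple | None = None     # None: hairpin+helix fold
    extended_template: tuple = STRAND_TEMPLATE
    noise_sd_deg: float = 8.0
    mixing: float = 0.7                   # fraction of compact frames
    transition: tuple[tuple[float, float], tuple[float, float]] = (
        (0.98, 0.02), (0.02, 0.98))       # rows: from CS, from ES
    frame_interval_ps: float = 100.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.mixing <= 1.0:
            raise ValueError("mixing must be in [0, 1]")
        T = np.asarray(self.transition, dtype=float)
        if T.shape != (2, 2) or not np.allclose(T.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if np.any(T < 0):
            raise ValueError("transition probabilities must be >= 0")
        if self.noise_sd_deg < 0:
            raise ValueError("noise sd must be >= 0")

    def template_angles(self, state: int) -> np.ndarray:
        """Per-residue (φ, ψ) template of state 0 (compact) or 1 (extended)."""
        if state == 0:
            if self.compact_template is None:
                return compact_fold_angles(self.n_residues)
            return _resolve_template(self.compact_template, self.n_residues)
        return _resolve_template(self.extended_template, self.n_residues)

    def resolved_sequence(self) -> str:
        seq = self.sequence
        if seq is None:
            if self.n_residues <= len(ABETA42_SEQUENCE):
                seq = ABETA42_SEQUENCE[:self.n_residues]
            else:
                reps = -(-self.n_residues // len(ABETA42_SEQUENCE))
                seq = (ABETA42_SEQUENCE * reps)[:self.n_residues]
        if len(seq) != self.n_residues:
            raise ValueError("sequence length does not match n_residues")
        return seq


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D given A, B, C: |CD| = bond, ∠BCD = angle,
    dihedral A-B-C-D = dihedral (natural-extension reference frame)."""
    theta = np.radians(angle_deg)
    chi = np.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(theta),
        bond * np.sin(theta) * np.cos(chi),
        bond * np.sin(theta) * np.sin(chi),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def backbone_topology(sequence: str,
                      hydrophobic_set=None) -> Topology:
    """Topology of the builder's backbone: N, CA, C, O, CB per residue.

    Glycine keeps a CB stub too — the builder is a geometric fixture, not
    a chemistry model.  Hydrophobic set defaults to the amyloid-beta
    collapse residues when the chain is long enough to contain them.
    """
    if hydrophobic_set is None:
        hydrophobic_set = tuple(r for r in DEFAULT_HYDROPHOBIC_SET
                                if r <= len(sequence))
    atoms = []
    names = []
    for aa in sequence:
        names.append(AA_THREE_LETTER.get(aa.upper(), "ALA"))
        atoms.append([
            AtomRecord("N", "N", ATOMIC_MASSES["N"], VDW_RADII["N"]),
            AtomRecord("CA", "C", ATOMIC_MASSES["C"], VDW_RADII["C"]),
            AtomRecord("C", "C", ATOMIC_MASSES["C"], VDW_RADII["C"]),
            AtomRecord("O", "O", ATOMIC_MASSES["O"], VDW_RADII["O"]),
            AtomRecord("CB", "C", ATOMIC_MASSES["C"], VDW_RADII["C"]),
        ])
    return Topology(residue_names=names, atoms=atoms,
                    hydrophobic_set=hydrophobic_set)


def build_backbone(phi_psi, sequence: str, time: float = 0.0,
                   trajectory_id: str = "traj") -> tuple[Topology, Frame]:
    """Build a backbone frame from per-residue (φ, ψ) by NeRF extension.

    ``phi_psi`` is a sequence of ``(phi, psi)`` pairs, one per residue;
    φ of residue 1 has no preceding carbonyl and is ignored.  Ideal bond
    lengths/angles and trans peptide bonds (ω = 180°) are used; the
    carbonyl O and a CB stub are placed from standard geometry.  The
    requested dihedrals are recovered exactly by ``geometry.phi_series``.
    """
    phi_psi = [(float(p), float(s)) for p, s in phi_psi]
    if len(phi_psi) != len(sequence):
        raise ValueError("phi_psi and sequence length mismatch")
    n_res = len(sequence)
    topo = backbone_topology(sequence)
    coords = np.zeros((topo.n_atoms, 3))

    # residue 1 seed: N at origin, CA on x, C in the xy-plane
    N = np.array([0.0, 0.0, 0.0])
    CA = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.radians(180.0 - _A_N_CA_C)
    C = CA + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])

    placed: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    for i in range(n_res):
        phi, psi = phi_psi[i]
        if i > 0:
            Np, CAp, Cp = placed[-1]
            N = _nerf(Np, CAp, Cp, _B_C_N, _A_CA_C_N, phi_psi[i - 1][1])
            CA = _nerf(CAp, Cp, N, _B_N_CA, _A_C_N_CA, _OMEGA)
            C = _nerf(Cp, N, CA, _B_CA_C, _A_N_CA_C, phi)
        placed.append((N, CA, C))

    for i, (N, CA, C) in enumerate(placed):
        res = i + 1
        psi = phi_psi[i][1]
        O = _nerf(N, CA, C, _B_C_O, _A_CA_C_O, psi + 180.0)
        CB = _place_cb(N, CA, C)
        coords[topo.atom_index(res, "N")] = N
        coords[topo.atom_index(res, "CA")] = CA
        coords[topo.atom_index(res, "C")] = C
        coords[topo.atom_index(res, "O")] = O
        coords[topo.atom_index(res, "CB")] = CB
    return topo, Frame(coords, time=time, trajectory_id=trajectory_id)


def build_hairpin(n_strand: int = 8,
                  strand: tuple[float, float] = (-125.0, 130.0),
                  turn: tuple[tuple[float, float], ...] = ((57.0, -126.0),
                                                           (-91.0, 5.0)),
                  ) -> tuple[Topology, Frame]:
    """Ideal two-strand antiparallel β-hairpin fixture.

    Two ``n_strand``-residue strands joined by a two-residue type II'-like
    β-turn, with dihedrals chosen so the strands hydrogen-bond in
    register.  Useful for exercising bridge/ladder detection in the
    secondary-structure assigner.
    """
    angles = [strand] * n_strand + list(turn) + [strand] * n_strand
    return build_backbone(angles, "A" * len(angles))


def _place_cb(N: np.ndarray, CA: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Tetrahedral CB position for an L-amino acid."""
    b1 = N - CA
    b1 /= np.linalg.norm(b1)
    b2 = C - CA
    b2 /= np.linalg.norm(b2)
    perp = np.cross(b1, b2)
    perp /= np.linalg.norm(perp)
    # direction with equal angles (110.6 deg) to both CA-N and CA-C
    target = np.cos(np.radians(_A_N_CA_CB))
    c12 = b1 @ b2
    alpha = target / (1.0 + c12)
    gamma2 = 1.0 - alpha * alpha * (2.0 + 2.0 * c12)
    gamma = np.sqrt(max(gamma2, 0.0))
    d = alpha * (b1 + b2) + gamma * perp      # + sign fixes the chirality
    return CA + _B_CA_CB * d / np.linalg.norm(d)


def _jittered_frame(base_angles: np.ndarray, noise_sd: float,
                    rng: np.random.Generator, sequence: str, time: float,
                    trajectory_id: str) -> Frame:
    angles = base_angles + rng.normal(0.0, noise_sd, base_angles.shape)
    _, frame = build_backbone(angles, sequence, time=time,
                              trajectory_id=trajectory_id)
    return frame


def generate_two_state_ensemble(
        spec: GeneratorSpec = GeneratorSpec(),
        n_frames: int = 1000,
        sasa_params: SasaParams = SasaParams(),
        min_separation: float = 200.0,
        max_retries: int = 3,
        check_sample: int = 50,
) -> tuple[Ensemble, np.ndarray]:
    """Two-population ensemble with planted compact/extended labels.

    Exactly ``round(mixing * n_frames)`` frames are compact (label 0,
    helical template, low hydrophobic SASA); the rest are extended
    (label 1, strand template).  Labels are shuffled in time.  The
    generator verifies on a subsample that the mean hydrophobic-SASA gap
    between the populations is at least ``min_separation`` Å² and redraws
    the jitter (bounded retries) otherwise; failure raises with advice to
    lower the dihedral noise.  Fully reproducible from ``spec.seed``.
    """
    sequence = spec.resolved_sequence()
    n_compact = int(round(spec.mixing * n_frames))
    base_labels = np.array([0] * n_compact + [1] * (n_frames - n_compact))
    for attempt in range(max_retries):
        rng = np.random.default_rng(
            np.random.SeedSequence([spec.seed, attempt]))
        labels = rng.permutation(base_labels)
        templates = (spec.template_angles(0), spec.template_angles(1))
        frames = []
        for k, lab in enumerate(labels):
            frames.append(_jittered_frame(
                templates[lab], spec.noise_sd_deg, rng,
                sequence, time=k * spec.frame_interval_ps,
                trajectory_id="traj"))
        ensemble = Ensemble(topology=backbone_topology(sequence),
                            frames=frames, group_id="synthetic")
        if _separation_ok(ensemble, labels, sasa_params, min_separation,
                          check_sample):
            return ensemble, labels
    raise ValueError(
        f"could not reach a {min_separation} Å² SASA separation between the "
        f"two populations; lower noise_sd_deg (currently "
        f"{spec.noise_sd_deg}°)"
    )


def _separation_ok(ensemble: Ensemble, labels: np.ndarray,
                   sasa_params: SasaParams, min_separation: float,
                   check_sample: int) -> bool:
    topo = ensemble.topology
    means = []
    for lab in (0, 1):
        idx = np.nonzero(labels == lab)[0][:check_sample]
        if idx.size == 0:
            return True  # single-population spec: nothing to separate
        vals = [hydrophobic_sasa(ensemble.frames[i], topo, sasa_params)
                for i in idx]
        means.append(np.mean(vals))
    return means[1] - means[0] >= min_separation


def generate_archetype_fingerprints(
        k: int, length: int, flip_prob: float, n_per_class: int,
        seed: int = 0, min_hamming: float = 0.3,
        max_resample: int = 100) -> tuple[np.ndarray, np.ndarray]:
    """Noisy copies of ``k`` random binary archetypes.

    Archetypes are resampled until every pair differs in at least
    ``min_hamming`` of the positions; members then get i.i.d. bit flips
    with probability ``flip_prob``.  Returns ``(fingerprints, labels)``
    with ``k * n_per_class`` rows.
    """
    if not 0 <= flip_prob <= 1:
        raise ValueError("flip_prob must be in [0, 1]")
    rng = np.random.default_rng(seed)
    for _ in range(max_resample):
        arch = rng.integers(0, 2, size=(k, length)).astype(np.uint8)
        if k == 1:
            break
        dists = [
            np.mean(arch[i] != arch[j])
            for i in range(k) for j in range(i + 1, k)
        ]
        if min(dists) >= min_hamming:
            break
    else:
        raise ValueError("could not sample archetypes with the requested "
                         "pairwise separation")
    labels = np.repeat(np.arange(k), n_per_class)
    F = arch[labels]
    flips = rng.random(F.shape) < flip_prob
    return (F ^ flips.astype(np.uint8)), labels


def generate_markov_trajectories(
        spec: GeneratorSpec = GeneratorSpec(),
        n_traj: int = 10, n_frames: int = 100,
        start_state: int = 0, build_frames: bool = True,
) -> tuple[Ensemble | None, "pd.DataFrame"]:
    """Two-state Markov-switching trajectories with the true state path.

    Each trajectory starts in ``start_state`` (0 = compact, 1 = extended)
    and evolves by ``spec.transition`` per saved frame.  Frames are drawn
    from the matching template population.  Returns the ensemble (or
    ``None`` when ``build_frames`` is off, for tests that only need the
    truth) and a DataFrame with columns ``trajectory``, ``time`` (ps) and
    ``state`` (0/1).
    """
    import pandas as pd

    sequence = spec.resolved_sequence()
    T = np.asarray(spec.transition)
    rng = np.random.default_rng(spec.seed)
    templates = (spec.template_angles(0), spec.template_angles(1))
    rows = []
    frames = []
    for t in range(n_traj):
        tid = f"traj{t:03d}"
        state = start_state
        for k in range(n_frames):
            time = k * spec.frame_interval_ps
            rows.append((tid, time, state))
            if build_frames:
                frames.append(_jittered_frame(
                    templates[state], spec.noise_sd_deg, rng,
                    sequence, time=time, trajectory_id=tid))
            state = int(rng.random() >= T[state, 0]) if state == 0 else \
                int(rng.random() < T[1, 1])
    truth = pd.DataFrame(rows, columns=["trajectory", "time", "state"])
    ensemble = None
    if build_frames:
        ensemble = Ensemble(topology=backbone_topology(sequence),
                            frames=frames, group_id="markov")
    return ensemble, truth


def random_phi_distributions(n_residues: int, n_samples: int = 50,
                             seed: int = 0,
                             centers=(-150.0, -60.0, 0.0, 60.0, 150.0),
                             spread: float = 15.0) -> dict[int, np.ndarray]:
    """Diverse per-residue φ distributions for J-coupling simulations.

    Residues cycle through dihedral basins whose centres span the range
    of cos(φ−60°) (≈ −0.87 … 1, including 0), so both trigonometric
    basis terms of the Karplus fit vary strongly across residues and the
    inverse problem is well conditioned.  1-based residue keys starting
    at 2 (residue 1 has no φ).
    """
    rng = np.random.default_rng(seed)
    out = {}
    for r in range(2, n_residues + 2):
        mu = centers[r % len(centers)] + rng.uniform(-20.0, 20.0)
        out[r] = rng.normal(mu, spread, n_samples)
    return out


def simulate_j_table(coeffs: KarplusCoefficients,
                     phi_samples: dict[int, np.ndarray],
                     noise_sd: float = 0.0, seed: int = 0
                     ) -> tuple[ObservableTable, dict[int, float]]:
    """Simulated per-residue J-coupling table with known truth.

    The calculated column holds the exact ensemble-mean Karplus value for
    each residue; the observed column adds Gaussian noise of standard
    deviation ``noise_sd`` Hz.  Returns the table and the noiseless truth
    (residue → mean J).
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    residues = sorted(phi_samples)
    truth = {r: float(np.mean(karplus_j(np.asarray(phi_samples[r]), coeffs)))
             for r in residues}
    calc = np.array([truth[r] for r in residues])
    obs = calc + rng.normal(0.0, noise_sd, len(residues))
    table = ObservableTable.from_arrays(residues, obs, calculated=calc,
                                        sd=np.full(len(residues), noise_sd))
    return table, truth
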