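"""Synthetic data generation with known ground truth.

Every input the analysis consumes can be generated here: two-state
equilibrium denaturation curves with linear baselines, V-shaped
chevrons with linear limbs, tryptophan emission spectra, and toy
backbone structures (ideal helix, extended strand, random coil) with
known contact maps.  Noise models follow how the data are fitted:
additive Gaussian noise on the equilibrium signal, multiplicative
log-normal noise on rate constants (rates are positive and fitted in
log space).  A seed fixes every realisation bit-for-bit.

The default variant family (:data:`FADD_VARIANTS`) encodes the
published thermodynamic and kinetic parameters of wild-type FADD and
its five circular permutants, anchored at a wild-type stability of
RT ln(kf/ku) = 5.96 kcal/mol so that equilibrium and kinetics are
mutually consistent for the wild type.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .chevron import ChevronDataset, ChevronParams
from .constants import RT_DEFAULT
from .equilibrium import DenaturationCurve, EquilibriumParams, signal_model
from .structure import ProteinStructure, Residue

# ------------------------------------------------------------- variants

#: Wild-type stability anchor, kcal/mol: RT ln(kf/ku) for the wild type.
WT_DG_H2O = RT_DEFAULT * np.log(940.0 / 0.04)  # ~5.963


@dataclass(frozen=True)
class VariantTruth:
    """Ground-truth parameter set for one synthetic variant."""

    variant_id: str
    ddg: float          # destabilisation vs wild type, kcal/mol
    m_eq: float         # kcal mol^-1 M^-1
    kf_h2o: float       # s^-1
    ku_h2o: float       # s^-1
    m_kf: float = 1.0   # M^-1
    m_ku: float = 0.8   # M^-1

    @property
    def dg_h2o(self) -> float:
        return WT_DG_H2O - self.ddg

    def equilibrium_params(self, alpha_N=355.0, beta_N=0.0,
                           alpha_D=372.0, beta_D=0.0) -> EquilibriumParams:
        """Two-state parameters with average-emission-wavelength-like
        baselines (folded Trp emission ~355 nm, unfolded ~372 nm)."""
        return EquilibriumParams(self.dg_h2o, self.m_eq, alpha_N, beta_N,
                                 alpha_D, beta_D)

    def chevron_params(self) -> ChevronParams:
        return ChevronParams(self.kf_h2o, self.m_kf, self.ku_h2o, self.m_ku)


#: Published parameter sets: wild type and the five circular permutants.
#: The unfolding m-value of CP_EF is about double the others.
FADD_VARIANTS: dict[str, VariantTruth] = {
    v.variant_id: v for v in [
        VariantTruth("WT",    0.00, 1.40,  940.0,  0.04),
        VariantTruth("CP_AB", 1.74, 1.59, 2300.0,  1.2),
        VariantTruth("CP_BC", 3.43, 1.34,  950.0, 24.3),
        VariantTruth("CP_CD", 2.24, 1.42, 1900.0, 26.1),
        VariantTruth("CP_DE", 4.44, 1.27, 2600.0,  4.9),
        VariantTruth("CP_EF", 2.77, 1.66,  450.0,  1.9, m_ku=1.6),
    ]
}

#: Default measurement grid, M urea
DEFAULT_UREA_GRID = np.arange(0.0, 8.25, 0.25)


# ------------------------------------------------------------ generators

def gen_equilibrium_curve(
    params: EquilibriumParams,
    urea_grid=DEFAULT_UREA_GRID,
    noise_sd: float = 0.0,
    seed: int = 0,
    variant_id: str = "synthetic",
) -> DenaturationCurve:
    """Two-state equilibrium curve with additive Gaussian noise.

    ``noise_sd = 0`` returns the exact model curve; the same seed
    reproduces the same realisation.
    """
    grid = np.asarray(urea_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("urea grid must be non-empty")
    if np.any(grid < 0):
        raise ValueError("urea concentrations must be non-negative")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    signal = np.asarray(signal_model(params, grid), dtype=float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        signal = signal + rng.normal(0.0, noise_sd, size=grid.shape)
    return DenaturationCurve(variant_id, grid, signal)


def gen_chevron(
    params: ChevronParams,
    urea_grid=DEFAULT_UREA_GRID,
    lognoise_sd: float = 0.0,
    seed: int = 0,
    variant_id: str = "synthetic",
) -> ChevronDataset:
    """Two-state chevron with multiplicative log-normal noise on k_obs."""
    grid = np.asarray(urea_grid, dtype=float)
    if grid.size == 0:
        raise ValueError("urea grid must be non-empty")
    if lognoise_sd < 0:
        raise ValueError("lognoise_sd must be non-negative")
    k = (params.kf_h2o * np.exp(-params.m_kf * grid)
         + params.ku_h2o * np.exp(params.m_ku * grid))
    if lognoise_sd > 0:
        rng = np.random.default_rng(seed)
        k = k * np.exp(rng.normal(0.0, lognoise_sd, size=grid.shape))
    return ChevronDataset(variant_id, grid, k)


def gen_emission_spectrum(
    wavelength_grid=None,
    peak_nm: float = 340.0,
    width_nm: float = 25.0,
    amplitude: float = 1.0,
    baseline: float = 0.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian-shaped tryptophan emission spectrum on 300-400 nm.

    Returns (wavelengths, intensities); intensities are clipped at zero
    so downstream averaging never sees negative weight.
    """
    if wavelength_grid is None:
        wavelength_grid = np.arange(300.0, 400.5, 0.5)
    lam = np.asarray(wavelength_grid, dtype=float)
    if lam.size < 2:
        raise ValueError("wavelength grid needs >= 2 points")
    if amplitude < 0 or baseline < 0:
        raise ValueError("negative intensities requested")
    f = baseline + amplitude * np.exp(-0.5 * ((lam - peak_nm) / width_nm) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        f = f + rng.normal(0.0, noise_sd, size=lam.shape)
    return lam, np.clip(f, 0.0, None)


# ------------------------------------------------------- toy structures

@dataclass(frozen=True)
class ToyStructureSpec:
    """Specification of a toy backbone chain."""

    n_residues: int
    geometry: str = "ideal_helix"  # ideal_helix | extended | random_coil
    seed: int = 0

    def __post_init__(self):
        if self.n_residues < 2:
            raise ValueError("need at least 2 residues")
        if self.geometry not in ("ideal_helix", "extended", "random_coil"):
            raise ValueError(f"unknown geometry {self.geometry!r}")


# backbone geometry (lengths A, angles deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8

# ideal alpha-helix dihedrals (phi, psi); extended beta-strand values
_HELIX_PHI, _HELIX_PSI = -57.0, -47.0
_EXT_PHI, _EXT_PSI = -135.0, 135.0


def _place(a, b, c, bond: float, angle_deg: float, dihedral_deg: float
           ) -> np.ndarray:
    """Natural extension reference frame: position of atom D given chain
    A-B-C, the C-D bond length, B-C-D angle and A-B-C-D dihedral."""
    ang = np.deg2rad(angle_deg)
    tor = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(tor),
        bond * np.sin(ang) * np.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_toy_structure(spec: ToyStructureSpec) -> ProteinStructure:
    """Full-backbone (N, CA, C, O) toy chain of alanines.

    ``ideal_helix`` uses phi = -57, psi = -47 degrees (1.5 A rise, ~100
    degree twist per residue), which places every interior i -> i+4
    hydrogen bond; ``extended`` uses beta-strand dihedrals and forms
    none; ``random_coil`` draws dihedrals reproducibly from the seed.
    """
    n = spec.n_residues
    if spec.geometry == "ideal_helix":
        phis = np.full(n, _HELIX_PHI)
        psis = np.full(n, _HELIX_PSI)
    elif spec.geometry == "extended":
        phis = np.full(n, _EXT_PHI)
        psis = np.full(n, _EXT_PSI)
    else:
        rng = np.random.default_rng(spec.seed)
        phis = rng.uniform(-180.0, 180.0, n)
        psis = rng.uniform(-180.0, 180.0, n)
    return _build_backbone(phis, psis)


def _build_backbone(phis, psis, res_name: str = "ALA") -> ProteinStructure:
    """Chain from per-residue (phi, psi), omega fixed trans (180 deg)."""
    n = len(phis)
    N = [None] * n
    CA = [None] * n
    C = [None] * n
    O = [None] * n
    # first residue in a canonical frame
    N[0] = np.zeros(3)
    CA[0] = np.array([_B_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(n - 1):
        N[i + 1] = _place(N[i], CA[i], C[i], _B_C_N, _A_CA_C_N, psis[i])
        CA[i + 1] = _place(CA[i], C[i], N[i + 1], _B_N_CA, _A_C_N_CA, 180.0)
        C[i + 1] = _place(C[i], N[i + 1], CA[i + 1], _B_CA_C, _A_N_CA_C,
                          phis[i + 1])
    for i in range(n):
        # carbonyl O opposite the next amide: dihedral N-CA-C-O = psi + 180
        O[i] = _place(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, psis[i] + 180.0)
    residues = [
        Residue(i + 1, res_name,
                {"N": N[i], "CA": CA[i], "C": C[i], "O": O[i]})
        for i in range(n)
    ]
    return ProteinStructure(residues)


#: Helix lengths of the synthetic death-domain mimic; each helix of
#: length n contributes n - 2 assignable helical residues, so these six
#: (16+13+12+16+14+14 = 85) give 73 helical residues in total.
MIMIC_HELIX_LENGTHS = (16, 13, 12, 16, 14, 14)


def build_death_domain_mimic(
    helix_lengths=MIMIC_HELIX_LENGTHS, spacing: float = 40.0
) -> ProteinStructure:
    """Synthetic stand-in for a six-helix death-domain fold.

    This is NOT an experimental structure: it concatenates six ideal
    alpha-helices into one chain, translating each helix far from the
    others so no inter-helix hydrogen bonds form.  It exists so that
    helix counting can be exercised on a death-domain-sized input with
    an exactly known answer (73 helical residues for the default helix
    lengths).
    """
    residues: list[Residue] = []
    idx = 0
    for h, hl in enumerate(helix_lengths):
        helix = build_toy_structure(ToyStructureSpec(hl, "ideal_helix"))
        offset = np.array([0.0, 0.0, h * spacing])
        for res in helix.residues:
            idx += 1
            atoms = {k: v + offset for k, v in res.atoms.items()}
            residues.append(Residue(idx, res.name, atoms))
    return ProteinStructure(residues)


# ------------------------------------------------------------- toy maps

#: Helix-helix interfaces of the six-helix bundle topology: sequential
#: neighbours pack against each other, bundle 1 is helices (1, 5, 6),
#: bundle 2 is (2, 3, 4), and the two bundles meet through the central
#: core pairings (1-4) and (2-5).  0-based helix indices.
BUNDLE_INTERFACES = (
    (0, 1), (1, 2), (2, 3), (3, 4), (4, 5),   # sequential packing
    (0, 4), (0, 5), (4, 5),                   # bundle 1
    (1, 3), (2, 3),                           # bundle 2
    (0, 3), (1, 4),                           # central core
)


def bundle_contact_map(
    helix_lengths=MIMIC_HELIX_LENGTHS,
    loop_length: int = 5,
    interface_atom_pairs: int = 3,
    interfaces=BUNDLE_INTERFACES,
) -> tuple["ContactMap", list[int]]:
    """Contact map of a six-helix-bundle-like topology, plus loop cuts.

    Intra-helix contacts (the dominant, local part) carry the atom-pair
    weights measured on an actual ideal-helix backbone at a 6 A cutoff;
    each helix-helix interface contributes five aligned residue pairs of
    ``interface_atom_pairs`` atom pairs around the helix midpoints.
    Returns the map and the residue positions at the midpoints of the
    five inter-helix loops — the permutation sites available to a
    designer who opens new termini only in loops.
    """
    from .structure import ContactMap, contact_map as _cm

    starts, pos = [], 1
    for hl in helix_lengths:
        starts.append(pos)
        pos += hl + loop_length
    L = pos - loop_length - 1
    helices = [list(range(s, s + hl)) for s, hl in zip(starts, helix_lengths)]

    contacts: dict[tuple[int, int], int] = {}
    for h, hl in zip(helices, helix_lengths):
        toy = build_toy_structure(ToyStructureSpec(hl, "ideal_helix"))
        for i, j, n in _cm(toy, cutoff=6.0, min_seq_sep=1).contacts:
            contacts[(h[0] + i - 1, h[0] + j - 1)] = n
    for a, b in interfaces:
        ha, hb = helices[a], helices[b]
        ma, mb = len(ha) // 2, len(hb) // 2
        for off in (-2, -1, 0, 1, 2):
            i, j = ha[ma + off], hb[mb - off]
            if i > j:
                i, j = j, i
            contacts[(i, j)] = contacts.get((i, j), 0) + interface_atom_pairs
    loop_cuts = [h[-1] + loop_length // 2 + 1 for h in helices[:-1]]
    cl = [(i, j, n) for (i, j), n in sorted(contacts.items())]
    return ContactMap(L, cl, cutoff=6.0), loop_cuts


def long_range_contact_map(chain_length: int = 110,
                           n_contacts: int = 31) -> "ContactMap":
    """Sandwich-like map with exclusively long-range contacts: residue i
    pairs with residue L+1-i (strand-reversal pairing), no local
    contacts at all.  The antithesis of the helix-bundle map."""
    from .structure import ContactMap

    contacts = [(i, chain_length + 1 - i, 1)
                for i in range(20, 20 + n_contacts)]
    return ContactMap(chain_length, contacts, cutoff=6.0)


# ---------------------------------------------------------------- tables

def curves_to_frame(curves) -> "pandas.DataFrame":  # noqa: F821
    """Long-format table (variant, urea_M, signal) for CSV export."""
    import pandas as pd

    rows = [
        {"variant": c.variant_id, "urea_M": d, "signal": s}
        for c in curves for d, s in zip(c.urea, c.signal)
    ]
    return pd.DataFrame(rows)


def chevrons_to_frame(datasets) -> "pandas.DataFrame":  # noqa: F821
    """Long-format table (variant, urea_M, k_obs_s) for CSV export."""
    import pandas as pd

    rows = [
        {"variant": c.variant_id, "urea_M": d, "k_obs_s": k}
        for c in datasets for d, k in zip(c.urea, c.k_obs)
    ]
    return pd.DataFrame(rows)


def frame_to_curves(df) -> list[DenaturationCurve]:
    """Inverse of :func:`curves_to_frame`."""
    return [
        DenaturationCurve(vid, g["urea_M"].to_numpy(), g["signal"].to_numpy())
        for vid, g in df.groupby("variant", sort=False)
    ]


def frame_to_chevrons(df) -> list[ChevronDataset]:
    """Inverse of :func:`chevrons_to_frame`."""
    return [
        ChevronDataset(vid, g["urea_M"].to_numpy(), g["k_obs_s"].to_numpy())
        for vid, g in df.groupby("variant", sort=False)
    ]
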