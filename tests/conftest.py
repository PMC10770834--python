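import numpy as np
import pytest

from bindscope import EmissionSpectrum, TitrationSeries

# Published reference values used across tests: binding constants by
# temperature and HOMO/LUMO energies (eV) with the derived descriptor
# rows they imply.
KB_BY_TEMPERATURE = {298.15: 3.1e4, 308.15: 3.3e4, 318.15: 3.6e4}

ORBITAL_TABLE = {
    "free digitoxin": {
        "HOMO": -6.507, "LUMO": -0.933,
        "Energy gap": 5.574, "Chemical potential": -3.72,
        "Global hardness": 2.787, "Ionization potential": 6.507,
        "Electron affinity": 0.933, "Electronegativity": 3.72,
        "Electrophilicity": 2.482669537,
    },
    "conformer 1": {
        "HOMO": -6.41, "LUMO": -0.911,
        "Energy gap": 5.499, "Chemical potential": -3.6605,
        "Global hardness": 2.7495, "Ionization potential": 6.41,
        "Electron affinity": 0.911, "Electronegativity": 3.6605,
        "Electrophilicity": 2.436672168,
    },
    "conformer 2": {
        "HOMO": -6.541, "LUMO": -0.85,
        "Energy gap": 5.691, "Chemical potential": -3.6955,
        "Global hardness": 2.8455, "Ionization potential": 6.541,
        "Electron affinity": 0.85, "Electronegativity": 3.6955,
        "Electrophilicity": 2.399704841,
    },
    "conformer 3": {
        "HOMO": -6.509, "LUMO": -1.36,
        "Energy gap": 5.149, "Chemical potential": -3.9345,
        "Global hardness": 2.5745, "Ionization potential": 6.509,
        "Electron affinity": 1.36, "Electronegativity": 3.9345,
        "Electrophilicity": 3.006465382,
    },
}


def flat_spectrum(level, concentration, grid=None, temperature=298.15):
    """Spectrum with a constant intensity across a small grid."""
    if grid is None:
        grid = np.arange(330.0, 351.0)
    return EmissionSpectrum(
        wavelengths=grid,
        intensities=np.full(grid.size, float(level)),
        excitation_wavelength=295.0,
        temperature=temperature,
        ligand_concentration=concentration,
    )


def hyperbolic_series(kb, delta_f_max, concentrations, f0=500.0, temperature=298.15):
    """Noiseless titration whose dF follows the 1:1 binding hyperbola."""
    spectra = [flat_spectrum(f0, 0.0, temperature=temperature)]
    for c in concentrations:
        df = delta_f_max * kb * c / (1.0 + kb * c)
        spectra.append(flat_spectrum(f0 + df, c, temperature=temperature))
    return TitrationSeries(spectra=spectra)


def brute_force_min_rmsd(reference, mobile, step_deg=2.0):
    """Exhaustive rotation-grid oracle for the optimal superposition rmsd.

    Scans z-y-z Euler angles on a uniform grid after centring both
    coordinate sets; independent of the SVD route.
    """
    p = mobile - mobile.mean(axis=0)
    q = reference - reference.mean(axis=0)
    step = np.deg2rad(step_deg)
    gammas = np.arange(0, 2 * np.pi, step)
    cg, sg = np.cos(gammas), np.sin(gammas)
    # innermost z-rotation applied to p for every gamma at once: (G, n, 3)
    pg = np.empty((gammas.size, p.shape[0], 3))
    pg[:, :, 0] = cg[:, None] * p[None, :, 0] - sg[:, None] * p[None, :, 1]
    pg[:, :, 1] = sg[:, None] * p[None, :, 0] + cg[:, None] * p[None, :, 1]
    pg[:, :, 2] = p[None, :, 2]
    best = np.inf
    for a in np.arange(0, 2 * np.pi, step):
        rza = np.array([[np.cos(a), -np.sin(a), 0],
                        [np.sin(a), np.cos(a), 0], [0, 0, 1]])
        for b in np.arange(0, np.pi + step / 2, step):
            ryb = np.array([[np.cos(b), 0, np.sin(b)], [0, 1, 0],
                            [-np.sin(b), 0, np.cos(b)]])
            m = rza @ ryb
            rotated = pg @ m.T
            d2 = ((rotated - q[None]) ** 2).sum(axis=2).mean(axis=1)
            best = min(best, float(d2.min()))
    return float(np.sqrt(best))


@pytest.fixture
def table1_kb():
    return dict(KB_BY_TEMPERATURE)


@pytest.fixture
def orbital_table():
    return {k: dict(v) for k, v in ORBITAL_TABLE.items()}
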