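import numpy as np
import pytest

from confokit import simulate

Q_GRID = np.linspace(0.002, 0.5, 501)


@pytest.fixture(scope="session")
def oligomer_curves():
    """Debye curves of the four oligomer fixtures on the standard q grid."""
    models = simulate.default_oligomer_models()
    return {name: simulate.debye_curve(m, Q_GRID) for name, m in models.items()}


@pytest.fixture(scope="session")
def sphere_curve():
    """Debye curve of a filled sphere sized to the measured Rg (47.6 Å)."""
    radius = 47.6 / np.sqrt(3.0 / 5.0)
    model = simulate.bead_sphere(radius, spacing=6.0)
    q = np.linspace(0.005, 0.35, 300)
    return simulate.debye_curve(model, q), radius
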