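import warnings

import pytest

import cytomech as cm

# tabulated subcomponent parameters of the two reference cell types:
# (role, E_MPa, nu, C10_MPa, D1_perMPa)
CELLTYPE1_ROWS = [
    ("cytoplasm", 1.28e-3, 0.37, 2.33e-4, 1.22e3),
    ("microtubule", 1.53e4, 0.38, 2.78e3, 9.39e-5),
    ("microfilament", 3.32e4, 0.38, 6.02e3, 4.33e-5),
    ("membrane", 1.28e-2, 0.30, 2.46e-3, 1.88e2),
    ("nucleus", 5.11e-3, 0.37, 9.33e-4, 3.05e2),
]
CELLTYPE2_ROWS = [
    ("cytoplasm", 1.00e-4, 0.37, 1.83e-5, 1.56e4),
    ("microtubule", 1.20e3, 0.38, 2.17e2, 1.20e-3),
    ("microfilament", 2.60e3, 0.38, 4.71e2, 5.54e-4),
    ("membrane", 1.00e-3, 0.30, 1.92e-4, 2.40e3),
    ("nucleus", 4.00e-4, 0.37, 7.30e-5, 3.90e3),
]

# cytoplasm SLS parameters shared by both reference sets
SLS_CYTOPLASM = dict(E_R=4.50e-4, tau_sigma=19.7, tau_epsilon=9.5)

#: printed stiffness ratio between the reference cell types
Q_PRINTED = 12.78


@pytest.fixture(scope="session")
def celltype1():
    return cm.load_material_set("celltype1")


@pytest.fixture(scope="session")
def celltype2():
    return cm.load_material_set("celltype2")


@pytest.fixture(scope="session")
def graph1(celltype1):
    return cm.build_tensegrity(8.0, "config1", materials=celltype1)


@pytest.fixture(scope="session")
def graph2(celltype1):
    return cm.build_tensegrity(8.0, "config2", materials=celltype1)


def _prestress_quiet(g, prestrain=0.01):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=cm.tensegrity.StrutBucklingWarning)
        return cm.apply_prestress(g, cable_prestrain=prestrain)


@pytest.fixture(scope="session")
def prestressed1(graph1):
    return _prestress_quiet(graph1)


@pytest.fixture(scope="session")
def prestressed2(graph2):
    return _prestress_quiet(graph2)
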