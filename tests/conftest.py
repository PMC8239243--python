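import pytest

from coordchar import parse_formula

# The Cu(II) bis-sulfaclozine chlorido complex, written with the ligand
# group expanded: [Cu(C10H9ClN4O2S)2Cl]Cl == CuC20H18Cl4N8O4S2.
CU_COMPLEX = "Cu(C10H9ClN4O2S)2Cl2"
CU_COMPLEX_HYDRATE = "CuC20H18Cl4N8O4S2.2H2O"
NI_COMPLEX_HYDRATE = "Ni(C10H9ClN4O2S)2Cl2.2H2O"


@pytest.fixture
def cu_complex():
    return parse_formula(CU_COMPLEX)


@pytest.fixture
def cu_complex_hydrate():
    return parse_formula(CU_COMPLEX_HYDRATE)


@pytest.fixture
def ni_complex_hydrate():
    return parse_formula(NI_COMPLEX_HYDRATE)
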