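import pytest

from hadscreen.registry import HADRegistry, PrescriptionRow, RegistryEntry, VisitRecord


@pytest.fixture(scope="session")
def toy_registry() -> HADRegistry:
    """Minimal registry: one HAD per type plus implicit non-HADs."""
    return HADRegistry(
        {
            "Digoxin": RegistryEntry(True, "general", "CVS"),
            "Warfarin": RegistryEntry(True, "general", "BIG"),
            "Morphine": RegistryEntry(True, "narcotic_psychotropic", "CNS"),
            "Pseudoephedrine": RegistryEntry(True, "narcotic_psychotropic", "ANS"),
            "Regular insulin": RegistryEntry(True, "general", "END"),
            "Methotrexate": RegistryEntry(True, "iv_cytotoxic", "Tumor"),
        }
    )


def make_visit(txn="V1", gender="female", age=50, icd10s=("X",), drugs=("Paracetamol",)):
    return VisitRecord(
        txn=txn, gender=gender, age=age, icd10_set=frozenset(icd10s), drugs=tuple(drugs)
    )


def make_row(txn="V1", gender="female", age=50, icd10="X", drug="Paracetamol"):
    return PrescriptionRow(
        txn=txn, gender=gender, age=age, icd10=icd10, drug_code=drug, drug_name=drug
    )


@pytest.fixture(scope="session")
def visit_factory():
    return make_visit


@pytest.fixture(scope="session")
def row_factory():
    return make_row
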