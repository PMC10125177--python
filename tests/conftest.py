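"""Shared fixtures: expensive models are built once per session."""

from __future__ import annotations

import numpy as np
import pytest

from aushell.builder import BuilderConfig, FormulationSpec, build_functionalized_cluster
from aushell.fixtures import make_toy_cluster, toy_drug_payload, toy_peptide_payload
from aushell.ligands import conjugate_payload, elongate_conformer, make_peg_linker
from aushell.structures import generate_reference_cluster


@pytest.fixture(scope="session")
def reference_model():
    """The idealized Au144(p-MBA)60 reference cluster."""
    return generate_reference_cluster()


@pytest.fixture(scope="session")
def peptide_template():
    """Long-linker PEG-peptide conjugate (synthetic glycine stand-in)."""
    linker = elongate_conformer(make_peg_linker(6, 11))
    return elongate_conformer(conjugate_payload(linker, toy_peptide_payload()))


@pytest.fixture(scope="session")
def drug_template():
    """Short-linker PEG-drug conjugate (synthetic ring-amine stand-in)."""
    linker = elongate_conformer(make_peg_linker(3, 11))
    return elongate_conformer(conjugate_payload(linker, toy_drug_payload()))


@pytest.fixture(scope="session")
def default_build(reference_model, peptide_template, drug_template):
    """One default 2:1 build (10 peptides + 5 drugs) at a fixed seed."""
    cfg = BuilderConfig(seed=7)
    form = FormulationSpec("pep", "drug", (2, 1), 10, 5)
    built, traces = build_functionalized_cluster(
        reference_model, form, peptide_template, drug_template, cfg)
    return built, traces


@pytest.fixture()
def toy_cluster():
    return make_toy_cluster(3, seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
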