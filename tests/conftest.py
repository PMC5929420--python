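from __future__ import annotations

import pytest

from pytarg import FixtureScenario, PyTargConfig, fullconstrain, make_model, make_profiles

MINI_SBML = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="mini" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
      <species id="B" compartment="c" hasOnlySubstanceUnits="false"
               boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb_m10" value="-10" constant="true"/>
      <parameter id="lb_0" value="0" constant="true"/>
      <parameter id="ub_1000" value="1000" constant="true"/>
    </listOfParameters>
    <fbc:listOfGeneProducts>
      <fbc:geneProduct fbc:id="G_g1" fbc:label="g1"/>
      <fbc:geneProduct fbc:id="G_g2" fbc:label="g2"/>
    </fbc:listOfGeneProducts>
    <listOfReactions>
      <reaction id="EX_A" reversible="true" fast="false"
                fbc:lowerFluxBound="lb_m10" fbc:upperFluxBound="ub_1000">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
      <reaction id="R1" reversible="false" fast="false"
                fbc:lowerFluxBound="lb_0" fbc:upperFluxBound="ub_1000">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <fbc:geneProductAssociation>
          <fbc:or>
            <fbc:geneProductRef fbc:geneProduct="G_g1"/>
            <fbc:geneProductRef fbc:geneProduct="G_g2"/>
          </fbc:or>
        </fbc:geneProductAssociation>
      </reaction>
      <reaction id="BIOMASS" reversible="false" fast="false"
                fbc:lowerFluxBound="lb_0" fbc:upperFluxBound="ub_1000">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="BIOMASS" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


@pytest.fixture(scope="session")
def config() -> PyTargConfig:
    return PyTargConfig()


@pytest.fixture(scope="session")
def chain3():
    return make_model(FixtureScenario("CHAIN3"))


@pytest.fixture(scope="session")
def parallel():
    return make_model(FixtureScenario("PARALLEL"))


@pytest.fixture(scope="session")
def selective():
    return make_model(FixtureScenario("SELECTIVE"))


@pytest.fixture(scope="session")
def chain3_constrained(chain3, config):
    profile, _ = make_profiles(FixtureScenario("CHAIN3"))
    return fullconstrain(chain3, profile, config)


@pytest.fixture(scope="session")
def parallel_constrained(parallel, config):
    profile, _ = make_profiles(FixtureScenario("PARALLEL"))
    return fullconstrain(parallel, profile, config)


@pytest.fixture(scope="session")
def selective_pair(selective, config):
    """(target, reference) constrained SELECTIVE models."""
    target_prof, ref_prof = make_profiles(FixtureScenario("SELECTIVE"))
    return (
        fullconstrain(selective, target_prof, config),
        fullconstrain(selective, ref_prof, config),
    )


@pytest.fixture()
def mini_sbml_path(tmp_path):
    path = tmp_path / "mini.xml"
    path.write_text(MINI_SBML)
    return path
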