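"""Structural SBML Level 3 export of the assembled reaction network.

Writes species, one compartment and every reaction with its reactant /
product stoichiometry.  Kinetic laws are not exported: the document is
meant for cross-checking the network structure (stoichiometry, moiety
conservation, reachability) in independent tools, not for re-simulation.
"""

from __future__ import annotations

import re
from pathlib import Path

from lxml import etree

from .model import ModelSpec

__all__ = ["export_sbml"]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


def _sid(name: str) -> str:
    """Turn a species/reaction name into a valid SBML SId."""
    sid = re.sub(r"[^A-Za-z0-9_]", "_", name)
    if not re.match(r"[A-Za-z_]", sid):
        sid = "s_" + sid
    return sid


def export_sbml(model: ModelSpec, path: str | Path) -> None:
    nsmap = {None: SBML_NS}
    sbml = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    doc = etree.SubElement(sbml, "model", id="acyl_acp_coa_competition",
                           name="fatty acid / phospholipid synthesis with "
                                "acyl-ACP vs acyl-CoA competition")

    compartments = etree.SubElement(doc, "listOfCompartments")
    etree.SubElement(compartments, "compartment", id="cytosol",
                     constant="true", spatialDimensions="3", size="1")

    species_el = etree.SubElement(doc, "listOfSpecies")
    for sp in model.species:
        etree.SubElement(
            species_el, "species",
            id=_sid(sp), name=sp, compartment="cytosol",
            hasOnlySubstanceUnits="false",
            boundaryCondition="true" if sp in model.clamped else "false",
            constant="false",
        )

    reactions_el = etree.SubElement(doc, "listOfReactions")
    for rxn in model.reactions:
        r_el = etree.SubElement(reactions_el, "reaction", id=_sid(rxn.name),
                                name=rxn.name, reversible="false")
        reactants = {s: -c for s, c in rxn.stoich.items() if c < 0}
        products = {s: c for s, c in rxn.stoich.items() if c > 0}
        if reactants:
            lo = etree.SubElement(r_el, "listOfReactants")
            for s, c in reactants.items():
                etree.SubElement(lo, "speciesReference", species=_sid(s),
                                 stoichiometry=str(c), constant="true")
        if products:
            lo = etree.SubElement(r_el, "listOfProducts")
            for s, c in products.items():
                etree.SubElement(lo, "speciesReference", species=_sid(s),
                                 stoichiometry=str(c), constant="true")

    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)
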