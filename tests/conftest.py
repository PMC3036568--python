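"""Shared fixtures: tiny hand-built connectome models and generated volumes."""

from __future__ import annotations

import itertools

import pytest

from iplconnect import (
    AnnotationModel,
    GeneratorConfig,
    Location,
    LocationLink,
    Structure,
    StructureLink,
    VolumeMeta,
    build_graph,
    generate_connectome,
)


class ModelBuilder:
    """Programmatic construction of small annotation models."""

    def __init__(self, meta: VolumeMeta | None = None):
        self.model = AnnotationModel(meta=meta or VolumeMeta(slice_count=100))
        self._ids = itertools.count(1)
        self._locs = itertools.count(1)

    def cell(self, cell_class: str = "CELL") -> int:
        cid = next(self._ids)
        self.model.structures[cid] = Structure(id=cid, kind="cell", cell_class=cell_class)
        return cid

    def contact(
        self,
        src_cell: int,
        tgt_cell: int,
        contact_type: str = "conventional_synapse",
        channel: str = "",
        src_compartment: str = "terminal",
        tgt_compartment: str = "dendrite",
    ) -> tuple[int, int]:
        """Create one child per endpoint plus the joining structure link."""
        c1, c2 = next(self._ids), next(self._ids)
        self.model.structures[c1] = Structure(
            id=c1, kind="child", parent_id=src_cell,
            contact_type=contact_type, compartment=src_compartment,
        )
        self.model.structures[c2] = Structure(
            id=c2, kind="child", parent_id=tgt_cell,
            contact_type=contact_type, compartment=tgt_compartment,
        )
        directed = contact_type in ("conventional_synapse", "ribbon_synapse", "cistern_contact")
        self.model.structure_links.append(StructureLink(c1, c2, directed, channel))
        return c1, c2

    def location(self, sid: int, z: int, x: float, y: float, r: float = 5.0) -> int:
        lid = next(self._locs)
        self.model.locations[lid] = Location(lid, sid, z, x, y, r)
        return lid

    def link(self, a: int, b: int) -> None:
        self.model.location_links.append(LocationLink(a, b))

    def build(self) -> AnnotationModel:
        self.model.validate()
        return self.model


@pytest.fixture
def builder() -> ModelBuilder:
    return ModelBuilder()


@pytest.fixture
def local_network_model():
    """Rod BC presynaptic to an AII cell; the AII synapses onto an OFF cone
    bipolar cell and couples to an ON cone bipolar cell via a gap junction."""
    b = ModelBuilder()
    rod = b.cell("ROD_BC")
    aii = b.cell("AII_AC")
    off = b.cell("OFF_CBC")
    on = b.cell("ON_CBC")
    b.contact(rod, aii, "ribbon_synapse")
    b.contact(aii, off, "conventional_synapse")
    b.contact(aii, on, "gap_junction")
    return b.build(), {"rod": rod, "aii": aii, "off": off, "on": on}


@pytest.fixture
def aii_catalog_model():
    """An AII amacrine cell wired with the full seventeen-motif repertoire
    across twelve partner classes: dual-transmitter axonal-cell input,
    outputs to OFF ganglion and OFF GABA+ amacrine cells, GABA/peptide dual
    input, in/out contact with a second GABA+ amacrine class, OFF cone
    bipolar reciprocity, ON GABA+ amacrine input, coupling to ON cone /
    wide-field bipolar cells and another AII, wide-field ribbon input, AI
    amacrine input, and rod bipolar ribbon drive."""
    b = ModelBuilder()
    aii = b.cell("AII_AC")
    th1 = b.cell("TH1_AXC")
    gc = b.cell("GC")
    off_gac = b.cell("OFF_GABA_AC")
    pep = b.cell("GABA_PEPTIDE_AC")
    gac2 = b.cell("GABA_AC2")
    cba = b.cell("OFF_CBC")
    on_gac = b.cell("ON_GABA_AC")
    cbb = b.cell("ON_CBC")
    cbwb = b.cell("WF_ON_CBC")
    ai = b.cell("AI_AC")
    rod = b.cell("ROD_BC")
    aii2 = b.cell("AII_AC")

    b.contact(th1, aii, "conventional_synapse", channel="dopamine")   # 1
    b.contact(th1, aii, "conventional_synapse", channel="glutamate")  # 2
    b.contact(aii, gc, "conventional_synapse")                        # 3
    b.contact(aii, off_gac, "conventional_synapse")                   # 4
    b.contact(pep, aii, "conventional_synapse", channel="GABA")       # 5
    b.contact(pep, aii, "conventional_synapse", channel="peptide")    # 6
    b.contact(aii, gac2, "conventional_synapse")                      # 7
    b.contact(gac2, aii, "conventional_synapse")                      # 8
    b.contact(aii, cba, "conventional_synapse")                       # 9
    b.contact(cba, aii, "ribbon_synapse")                             # 10
    b.contact(on_gac, aii, "conventional_synapse")                    # 11
    b.contact(cbb, aii, "gap_junction")                               # 12
    b.contact(cbwb, aii, "gap_junction")                              # 13
    b.contact(cbwb, aii, "ribbon_synapse")                            # 14
    b.contact(ai, aii, "conventional_synapse")                        # 15
    b.contact(rod, aii, "ribbon_synapse")                             # 16
    b.contact(aii, aii2, "gap_junction")                              # 17
    return b.build(), aii


@pytest.fixture
def six_stage_chain_model():
    """Eight-cell fixture of the longest observed synaptic chain: an OFF
    cone bipolar cell drives two amacrine cells converging on a GABA+
    amacrine cell, which drives an AII amacrine cell, then another GABA+
    amacrine cell, a second OFF bipolar cell, and finally a ganglion cell —
    six synaptic stages end to end."""
    b = ModelBuilder()
    bc1 = b.cell("OFF_CBC")
    ac_a = b.cell("GABA_AC")
    ac_b = b.cell("GABA_AC")
    c6011 = b.cell("GABA_AC")
    aii = b.cell("AII_AC")
    c174 = b.cell("GABA_AC")
    bc2 = b.cell("OFF_CBC")
    gc = b.cell("GC")
    b.contact(bc1, ac_a)
    b.contact(bc1, ac_b)
    b.contact(ac_a, c6011)
    b.contact(ac_b, c6011)
    b.contact(c6011, aii)
    b.contact(aii, c174)
    b.contact(c174, bc2)
    b.contact(bc2, gc)
    names = dict(bc1=bc1, ac_a=ac_a, ac_b=ac_b, c6011=c6011, aii=aii,
                 c174=c174, bc2=bc2, gc=gc)
    return b.build(), names


@pytest.fixture(scope="session")
def generated():
    """Default synthetic connectome with its planted truth (seed 0)."""
    return generate_connectome(GeneratorConfig(seed=0))


@pytest.fixture(scope="session")
def generated_graph(generated):
    model, truth = generated
    return build_graph(model), truth
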