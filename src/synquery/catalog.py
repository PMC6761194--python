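"""The standard ten-query catalog for cortical synapse typing.

Five synapse types — glutamatergic (overall, VGluT1, VGluT2, VGluT1/VGluT2)
and GABAergic — each in a bipartite form and a tripartite form requiring an
adjacent glutamine-synthetase (astrocyte) punctum.  VGluT2 carries a
two-section span floor because its antibody also produces single-section
speckle background.
"""

from __future__ import annotations

from .query_engine import MarkerSpec, Query

#: Channel names used by the standard catalog.
SYNAPSIN, PSD95, VGLUT1, VGLUT2, GAD, GEPHYRIN, GS = (
    "synapsin", "PSD95", "VGluT1", "VGluT2", "GAD", "gephyrin", "GS")


def _m(channel: str, min_slices: int | None = None) -> MarkerSpec:
    return MarkerSpec(channel=channel, min_slices=min_slices)


def standard_queries(required_span: int = 1) -> dict[str, Query]:
    """Build the ten standard queries at a given base span requirement."""
    defs = {
        "Glutamatergic": ((_m(SYNAPSIN),), (_m(PSD95),), None),
        "Glutamatergic VGluT1": ((_m(SYNAPSIN), _m(VGLUT1)), (_m(PSD95),), None),
        "Glutamatergic VGluT2": ((_m(SYNAPSIN), _m(VGLUT2, 2)), (_m(PSD95),), None),
        "Glutamatergic VGluT1/VGluT2": (
            (_m(SYNAPSIN), _m(VGLUT1), _m(VGLUT2, 2)), (_m(PSD95),), None),
        "GABAergic": ((_m(SYNAPSIN), _m(GAD)), (_m(GEPHYRIN),), None),
    }
    out: dict[str, Query] = {}
    for name, (pre, post, astro) in defs.items():
        out[name] = Query(name=name, presynaptic=pre, postsynaptic=post,
                          astrocyte=astro, required_span=required_span)
        trip = f"{name} adjacent to astrocyte"
        # GS carries a two-section floor like VGluT2: peripheral astrocytic
        # processes are extended structures, and the floor suppresses
        # single-section background from triggering spurious tripartite calls
        out[trip] = Query(name=trip, presynaptic=pre, postsynaptic=post,
                          astrocyte=_m(GS, 2), required_span=required_span)
    return out


#: Bipartite ↔ tripartite pairing of the standard catalog.
TRIPARTITE_OF = {name: f"{name} adjacent to astrocyte"
                 for name in ("Glutamatergic", "Glutamatergic VGluT1",
                              "Glutamatergic VGluT2",
                              "Glutamatergic VGluT1/VGluT2", "GABAergic")}
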