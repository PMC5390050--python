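"""Analyte roster for the procyanidin method.

The method quantifies one monomeric flavan-3-ol class and the oligomeric
procyanidins dp2 through dp10.  The chromatography does not separate
(−)-epicatechin from (+)-catechin, so monomers are reported as a single
class; the calibration standard itself is authentic epicatechin.
"""

from __future__ import annotations

EPICATECHIN = "epicatechin"
MONOMERS = "monomers"

#: dp values covered by the indirect (RRF) calibration.
DP_RANGE = tuple(range(2, 11))

#: analyte ids in elution/reporting order
OLIGOMER_IDS = tuple(f"dp{d}" for d in DP_RANGE)
ANALYTE_IDS = (EPICATECHIN,) + OLIGOMER_IDS

#: ids accepted in sample peak tables ("monomers" is the sample-side label
#: for the unresolved catechin class, quantified with RRF = 1)
SAMPLE_ANALYTE_IDS = (MONOMERS,) + OLIGOMER_IDS

#: every id accepted anywhere in the pipeline
VALID_IDS = frozenset(ANALYTE_IDS) | {MONOMERS}
_VALID = VALID_IDS


def dp_of(analyte: str) -> int | None:
    """Degree of polymerisation of *analyte*, or None for the monomer class."""
    if analyte in (EPICATECHIN, MONOMERS):
        return None
    if analyte.startswith("dp"):
        try:
            d = int(analyte[2:])
        except ValueError:
            raise ValueError(f"unknown analyte id: {analyte!r}") from None
        if d in DP_RANGE:
            return d
    raise ValueError(f"unknown analyte id: {analyte!r}")


def is_oligomer(analyte: str) -> bool:
    return dp_of(analyte) is not None


def check_analyte(analyte: str) -> str:
    if analyte not in _VALID:
        raise ValueError(f"unknown analyte id: {analyte!r}")
    return analyte
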