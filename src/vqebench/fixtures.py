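"""Packaged integral fixtures.

``h2`` is molecular hydrogen in the minimal STO-3G basis at the equilibrium
bond length (0.7414 Angstrom): two spatial orbitals (bonding/antibonding),
two electrons, four spin orbitals.  The restricted-HF molecular-orbital
integrals are the widely tabulated reference values for this geometry, in
chemists' notation, with the nuclear repulsion as the core constant.  Small
enough for every cross-check (brute-force diagonalization, determinant CI,
UCCSD exactness) to run in milliseconds.

Synthetic fixtures of other sizes are produced on demand by
:func:`vqebench.hamiltonian.random_integral_set`.
"""

from __future__ import annotations

import io

from .errors import InputError
from .hamiltonian import IntegralSet, read_fcidump

__all__ = ["fixture_names", "fixture_integrals", "H2_FCIDUMP"]

H2_FCIDUMP = """\
&FCI NORB=2,NELEC=2,MS2=0,
 ORBSYM=1,1,
 ISYM=1,
&END
 0.6744931033260081   1   1   1   1
 0.6634720448605567   1   1   2   2
 0.1812875358123322   1   2   1   2
 0.6973979494693358   2   2   2   2
-1.2524635735648981   1   1   0   0
-0.4759487152209648   2   2   0   0
 0.7137539936876182   0   0   0   0
"""

_FIXTURES = {"h2": H2_FCIDUMP}


def fixture_names() -> list[str]:
    return sorted(_FIXTURES)


def fixture_integrals(name: str) -> IntegralSet:
    """Load a packaged fixture by name."""
    try:
        text = _FIXTURES[name]
    except KeyError:
        raise InputError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}"
        ) from None
    return read_fcidump(io.StringIO(text))
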