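"""The fixed feature universe of the FOI reading.

A reading annotates each phase image of each hand with a subset of 20
one-letter image-feature acronyms.  Encoded variables are named
``acronym + phase`` (e.g. ``"P2"`` = proximal interphalangeal joint signal
seen in phase 2), giving 20 x 3 = 60 binary indicators per patient.
"""

from __future__ import annotations

#: The 20 image-feature acronyms used in the reading.  Case matters:
#: ``r`` (finger-related) and ``R`` (Raynaud-type flow change) are distinct.
ACRONYMS: tuple[str, ...] = (
    "D", "P", "M", "C", "O",  # joint-related
    "r", "R",                 # finger-related
    "a", "I",                 # nail
    "V",                      # venous vessel
    "E", "B", "Y",            # connective tissue
    "F", "W",                 # skin
    "H", "S", "T", "U", "Z",  # later additions (veins at MCP, starry sky, ...)
)

#: Contrast-agent phases the reading is performed in.
PHASES: tuple[int, ...] = (1, 2, 3)

#: All 60 feature-phase column names in canonical order (phase-major within
#: acronym order): D1, D2, D3, P1, ...
FEATURE_NAMES: tuple[str, ...] = tuple(
    f"{a}{p}" for a in ACRONYMS for p in PHASES
)

#: The three diagnosis cohorts of the study.
DIAGNOSES: tuple[str, ...] = ("RA", "OA", "CTD")

#: Cohort sizes of the study population (before featureless-patient removal).
COHORT_SIZES: dict[str, int] = {"RA": 237, "OA": 231, "CTD": 141}

#: Feature-phase indicators that were never observed in the study's readings
#: and are dropped by the zero-column filter.
NEVER_OBSERVED: tuple[str, ...] = (
    "E1", "H1", "H2", "H3", "O1", "r2", "r3", "S2", "S3",
    "T1", "T2", "T3", "W1", "W2", "W3",
)

HANDS: tuple[str, ...] = ("left", "right")


def validate_feature_name(name: str) -> tuple[str, int]:
    """Split a feature-phase name like ``"P2"`` into ``("P", 2)``.

    Raises ``ValueError`` naming the offending id if the acronym is not in
    the 20-symbol universe or the phase is not 1-3.
    """
    if len(name) < 2 or name[-1] not in "123":
        raise ValueError(f"malformed feature-phase name: {name!r}")
    acronym, phase = name[:-1], int(name[-1])
    if acronym not in ACRONYMS:
        raise ValueError(f"unknown feature acronym: {acronym!r} (in {name!r})")
    return acronym, phase
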