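"""The four esophageal diagnostic classes and their clinical risk order.

Tissues are graded normal < BE-no-dysplasia < BE-with-dysplasia <
adenocarcinoma (BE = Barrett esophagus).  A tissue containing lesions of
several classes receives the most severe one as its label (the
highest-risk rule); a tissue with no lesions is normal.
"""

from __future__ import annotations

NORMAL = "normal"
BE_NO_DYSPLASIA = "be_no_dysplasia"
BE_WITH_DYSPLASIA = "be_with_dysplasia"
ADENOCARCINOMA = "adenocarcinoma"

#: Risk-ascending total order; index doubles as the integer class id.
CLASS_ORDER: tuple[str, ...] = (NORMAL, BE_NO_DYSPLASIA, BE_WITH_DYSPLASIA, ADENOCARCINOMA)

N_CLASSES = len(CLASS_ORDER)

_RISK = {c: i for i, c in enumerate(CLASS_ORDER)}


def class_index(name: str) -> int:
    """Integer id (= risk rank) of a class name; raises on unknown names."""
    try:
        return _RISK[name]
    except KeyError:
        raise ValueError(f"unknown class {name!r}; expected one of {CLASS_ORDER}") from None


def highest_risk(names) -> str:
    """Most severe class among ``names``; ``normal`` for an empty iterable."""
    names = list(names)
    if not names:
        return NORMAL
    return CLASS_ORDER[max(class_index(n) for n in names)]
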