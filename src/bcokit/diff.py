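"""Structured comparison of two BCOs and repeat-equivalence.

Two analyses are *repeat-equivalent* when every difference between their
BCOs lies in the provenance or usability domains: the described computation
— pipeline steps, execution environment, parameters, files, error
tolerances — is identical, so a colleague re-running either object performs
the same experiment.  The digital signature is excluded from comparison
(it seals content, it is not content).

Comparison is leaf-wise over the canonical JSON trees.  List elements are
compared positionally, except contributors (keyed by name) and parameters
(keyed by (param, step)) so that harmless reordering does not drown a
reviewer in noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

from . import canonical
from .model import BcoEnvelope

__all__ = ["ABSENT", "Difference", "DiffReport", "flatten_envelope",
           "diff_envelopes", "repeat_equivalent", "DIFF_CLASSES"]


class _Absent:
    def __repr__(self) -> str:
        return "<absent>"

    def __eq__(self, other: object) -> bool:
        return isinstance(other, _Absent)

    def __hash__(self) -> int:
        return hash("<absent>")


#: Sentinel for "no value at this path in that envelope".
ABSENT = _Absent()

DIFF_CLASSES = ("PROVENANCE_ONLY", "USABILITY_ONLY", "PARAMETRIC",
                "EXECUTION", "STRUCTURAL", "IO", "ERROR_DOMAIN")

# owning top-level member -> difference class.  The extension domain and any
# custom top-level member map to STRUCTURAL: content we cannot prove inert
# is conservatively treated as changing the computation.
_CLASS_BY_TOP = {
    "object_id": "PROVENANCE_ONLY",
    "bco_type": "PROVENANCE_ONLY",
    "spec_version": "PROVENANCE_ONLY",
    "provenance": "PROVENANCE_ONLY",
    "usability": "USABILITY_ONLY",
    "parametric": "PARAMETRIC",
    "execution": "EXECUTION",
    "description": "STRUCTURAL",
    "extension": "STRUCTURAL",
    "io": "IO",
    "error": "ERROR_DOMAIN",
}


@dataclass
class Difference:
    path: str
    left: Any
    right: Any
    domain: str

    def to_json_obj(self) -> dict:
        def j(v: Any) -> Any:
            return "<absent>" if isinstance(v, _Absent) else v
        return {"path": self.path, "left": j(self.left),
                "right": j(self.right), "domain": self.domain}


@dataclass
class DiffReport:
    differences: list[Difference] = field(default_factory=list)

    @property
    def classes(self) -> set[str]:
        return {_CLASS_BY_TOP.get(d.domain, "STRUCTURAL")
                for d in self.differences}

    def to_json_obj(self) -> dict:
        return {"differences": [d.to_json_obj() for d in self.differences],
                "classes": sorted(self.classes),
                "repeat_equivalent": repeat_equivalent(self)}


def _keyed_list(path: str, items: list) -> dict[str, Any] | None:
    """Key contributors by name and parameters by (param, step); positional
    elsewhere.  Falls back to positional when keys are missing/duplicated."""
    if path == "provenance.contributors":
        keys = [i.get("name") if isinstance(i, dict) else None for i in items]
    elif path == "parametric.parameters":
        keys = [f"{i.get('param')}@{i.get('step')}" if isinstance(i, dict)
                else None for i in items]
    else:
        return None
    if any(k is None for k in keys) or len(set(keys)) != len(keys):
        return None
    return dict(zip(keys, items))


def _flatten(node: Any, path: str, out: dict[str, Any]) -> None:
    if isinstance(node, dict):
        if not node:
            out[path] = {}
            return
        for k in sorted(node):
            _flatten(node[k], f"{path}.{k}" if path else k, out)
    elif isinstance(node, list):
        if not node:
            out[path] = []
            return
        keyed = _keyed_list(path, node)
        if keyed is not None:
            for k, v in keyed.items():
                _flatten(v, f"{path}[{k}]", out)
        else:
            for i, v in enumerate(node):
                _flatten(v, f"{path}[{i}]", out)
    else:
        out[path] = node


def flatten_envelope(env: BcoEnvelope) -> dict[str, Any]:
    """Leaf path → value map of the canonical tree, signature excluded."""
    tree = canonical.to_tree(env, include_signature=False)
    out: dict[str, Any] = {}
    _flatten(tree, "", out)
    return out


def _owning_domain(path: str) -> str:
    head = path.split(".", 1)[0]
    return head.split("[", 1)[0]


def diff_envelopes(a: BcoEnvelope, b: BcoEnvelope) -> DiffReport:
    """Leaf-wise differences between two envelopes, ordered by path.

    ``diff(a, a)`` is empty; ``diff(a, b)`` and ``diff(b, a)`` contain the
    same paths with left/right swapped.
    """
    fa, fb = flatten_envelope(a), flatten_envelope(b)
    diffs: list[Difference] = []
    for path in sorted(set(fa) | set(fb)):
        left = fa.get(path, ABSENT)
        right = fb.get(path, ABSENT)
        # bool is an int subtype in Python; true vs 1 must still differ
        differs = (left != right
                   or isinstance(left, bool) is not isinstance(right, bool))
        if differs:
            diffs.append(Difference(path=path, left=left, right=right,
                                    domain=_owning_domain(path)))
    return DiffReport(differences=diffs)


def repeat_equivalent(r: DiffReport) -> bool:
    """True iff all differences are provenance/usability only — the described
    computation is unchanged and a repeat run is the same experiment."""
    return r.classes <= {"PROVENANCE_ONLY", "USABILITY_ONLY"}
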