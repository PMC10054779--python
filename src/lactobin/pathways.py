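"""Pathway-template completeness scoring of a bin's functional annotations.

A pathway template is an ordered list of enzymatic steps, each satisfiable by
any of several EC numbers or function-name fragments.  The shipped templates
transcribe three proposed pathways for the candidate lactate utilizers —
glycolysis from glucose-6P to pyruvate plus its fermentative branches,
butyrate synthesis from acetyl-CoA, and chorismate synthesis with its
quinate entry branch — together with transporter/complex presence panels.
Completeness is the satisfied fraction of *required* steps; branch and entry
steps are reported but not required.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping

_EC_RE = re.compile(r"^\d+\.(\d+|-)\.(\d+|-)\.(\d+|-)$")


@dataclass(frozen=True)
class PathwayStep:
    label: str                      # figure-key number(s), e.g. "13" or "2/3"
    name: str
    alternatives: tuple[str, ...]   # EC numbers and/or name fragments
    required: bool


@dataclass(frozen=True)
class PathwayTemplate:
    name: str
    product: str
    steps: tuple[PathwayStep, ...]

    def step(self, label: str) -> PathwayStep:
        for s in self.steps:
            if s.label == label:
                return s
        raise KeyError(f"{self.name}: no step {label!r}")


@dataclass
class Annotation:
    function: str
    ecs: set[str] = field(default_factory=set)


# AnnotationSet: cds_id -> Annotation
AnnotationSet = Mapping[str, Annotation]


@dataclass
class PathwayCall:
    pathway: str
    satisfied_steps: list[str]
    missing_steps: list[str]
    completeness: float
    complete: bool


def is_ec(token: str) -> bool:
    return bool(_EC_RE.match(token))


def _normalize(text: str) -> str:
    return re.sub(r"\s+", " ", text.strip().lower())


def _load_tsv(name: str) -> list[dict[str, str]]:
    text = resources.files("lactobin.data").joinpath(name).read_text()
    rows: list[dict[str, str]] = []
    header: list[str] | None = None
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        cells = line.split("\t")
        if header is None:
            header = cells
        else:
            rows.append(dict(zip(header, cells)))
    return rows


def builtin_templates() -> list[PathwayTemplate]:
    """The shipped pathway templates (glycolysis, butyrate, chorismate)."""
    by_name: dict[str, dict] = {}
    for row in _load_tsv("pathway_templates.tsv"):
        t = by_name.setdefault(row["pathway"], {"product": row["product"], "steps": []})
        t["steps"].append(PathwayStep(
            label=row["step"],
            name=row["label"],
            alternatives=tuple(row["alternatives"].split(";")),
            required=row["required"] == "1",
        ))
    return [PathwayTemplate(name, d["product"], tuple(d["steps"]))
            for name, d in by_name.items()]


def builtin_panels() -> list[PathwayTemplate]:
    """Transporter/complex presence panels, evaluated like pathways."""
    by_name: dict[str, list[PathwayStep]] = {}
    for row in _load_tsv("presence_panels.tsv"):
        by_name.setdefault(row["panel"], []).append(PathwayStep(
            label=row["item"],
            name=row["item"],
            alternatives=tuple(row["alternatives"].split(";")),
            required=True,
        ))
    return [PathwayTemplate(name, name, tuple(steps))
            for name, steps in by_name.items()]


def _step_satisfied(step: PathwayStep, ecs: set[str], functions: list[str]) -> bool:
    for alt in step.alternatives:
        if is_ec(alt):
            if alt in ecs:
                return True
            if alt.endswith("-"):
                prefix = alt.rstrip("-")
                if any(e.startswith(prefix) for e in ecs):
                    return True
        else:
            needle = _normalize(alt)
            if any(needle in fn for fn in functions):
                return True
    return False


def evaluate_pathway(annotations: AnnotationSet, template: PathwayTemplate) -> PathwayCall:
    """Score one template against an annotation set.

    A step is satisfied iff any alternative matches: EC alternatives by exact
    match (prefix match when the template EC ends in '-'), name alternatives
    by case-insensitive substring of the annotation function text.
    Completeness is over required steps only; ``complete`` means every
    required step is satisfied.
    """
    ecs: set[str] = set()
    functions: list[str] = []
    for ann in annotations.values():
        ecs.update(ann.ecs)
        functions.append(_normalize(ann.function))
    satisfied, missing = [], []
    n_req = n_req_sat = 0
    for step in template.steps:
        ok = _step_satisfied(step, ecs, functions)
        (satisfied if ok else missing).append(step.label)
        if step.required:
            n_req += 1
            n_req_sat += ok
    completeness = n_req_sat / n_req if n_req else 1.0
    return PathwayCall(template.name, satisfied, missing, completeness,
                       complete=(n_req_sat == n_req))


def _product_template(name: str, product: str,
                      steps: Iterable[tuple[str, str, tuple[str, ...]]]) -> PathwayTemplate:
    return PathwayTemplate(name, product, tuple(
        PathwayStep(label, sname, alts, required=True) for label, sname, alts in steps
    ))


def end_product_templates() -> dict[str, PathwayTemplate]:
    """Sub-templates from the pyruvate node to each fermentation end product.

    Acetate is reachable either via phosphate acyltransferase + acetate
    kinase or in one step via AMP-forming acetyl-CoA synthetase; the
    synthetase therefore satisfies both steps of the two-step encoding.
    """
    butyrate = next(t for t in builtin_templates() if t.name == "butyrate")
    return {
        "formate": _product_template("formate", "formate", [
            ("14", "pyruvate formate lyase", ("2.3.1.54",)),
        ]),
        "acetate": _product_template("acetate", "acetate", [
            ("17|19", "acetyl transfer", ("phosphate acyltransferase", "6.2.1.1")),
            ("18|19", "acetate release", ("2.7.2.1", "6.2.1.1")),
        ]),
        "lactate": _product_template("lactate", "lactate", [
            ("13", "L-lactate dehydrogenase", ("1.1.1.27",)),
        ]),
        "ethanol": _product_template("ethanol", "ethanol", [
            ("20", "aldehyde dehydrogenase", ("1.2.1.3",)),
            ("21", "alcohol dehydrogenase", ("1.1.1.1",)),
        ]),
        "butyrate": butyrate,
    }


def end_product_report(annotations: AnnotationSet) -> dict[str, PathwayCall]:
    """Completeness call per fermentation end product."""
    return {product: evaluate_pathway(annotations, tmpl)
            for product, tmpl in end_product_templates().items()}


def read_annotations(path) -> dict[str, Annotation]:
    """Read an annotation TSV: cds_id, function, ec_numbers (comma-separated)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: dict[str, Annotation] = {}
    for r in df.itertuples():
        ecs = {e.strip() for e in str(r.ec_numbers).split(",") if e.strip()}
        out[str(r.cds_id)] = Annotation(str(r.function), ecs)
    return out
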