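"""Reading and writing network definition files (YAML).

The document has top-level keys ``inputs``, ``genes`` and ``reactions``,
one mapping per element mirroring the model dataclasses.  Unknown keys are
rejected.  The writer emits canonical key order and 12-significant-digit
floats so that write -> read -> write round-trips bit-exactly.
"""

from __future__ import annotations

import io

import yaml

from .model import (
    GeneSpec,
    InputSpec,
    NetworkSpec,
    ReactionSpec,
    SpeciesRef,
    TFBindingSpec,
)

__all__ = ["read_network", "write_network", "network_to_dict", "network_from_dict"]


def _num(x: float):
    if isinstance(x, int) or float(x).is_integer():
        return int(x)
    return float(f"{float(x):.12g}")


def _species(d, default_kind: str) -> SpeciesRef:
    if isinstance(d, str):
        return SpeciesRef(d, default_kind)
    _check_keys(d, {"name", "kind"}, "species")
    return SpeciesRef(d["name"], d.get("kind", default_kind))


def _check_keys(d: dict, allowed: set[str], what: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown keys in {what}: {sorted(unknown)}")


def network_to_dict(spec: NetworkSpec) -> dict:
    doc: dict = {"inputs": [], "genes": [], "reactions": []}
    for i in spec.inputs:
        doc["inputs"].append(
            {
                "species": i.species.name,
                "profile": i.profile,
                "amplitude": _num(i.amplitude),
                "period": _num(i.period),
                "phase": _num(i.phase),
                "baseline": _num(i.baseline),
            }
        )
    for g in spec.genes:
        doc["genes"].append(
            {
                "product": g.product.name,
                "logic": g.logic,
                "nu": _num(g.nu),
                "delta": _num(g.delta),
                "bindings": [
                    {
                        "tf": b.tf.name,
                        "lambda0": _num(b.lambda0),
                        "mu": _num(b.mu),
                        "role": b.role,
                    }
                    for b in g.bindings
                ],
                "rate_limiting_betas": [_num(b) for b in g.rate_limiting_betas],
                "fixed_delay_steps": int(g.fixed_delay_steps),
                "initial_level": _num(g.initial_level),
                "initial_state": g.initial_state,
            }
        )
    for r in spec.reactions:
        d = {
            "kind": r.kind,
            "substrates": [s.name for s in r.substrates],
            "complex": r.complex.name,
            "lambda": _num(r.lam),
            "mu": _num(r.mu),
            "deltas": [_num(x) for x in r.deltas],
        }
        if r.kind == "enzyme":
            d["enzyme"] = r.enzyme.name if r.enzyme else None
            d["product"] = r.product.name if r.product else None
            d["nu"] = _num(r.nu)
            d["product_initial"] = _num(r.product_initial)
        doc["reactions"].append(d)
    return doc


def network_from_dict(doc: dict) -> NetworkSpec:
    _check_keys(doc, {"inputs", "genes", "reactions"}, "network document")
    inputs = []
    for d in doc.get("inputs") or []:
        _check_keys(
            d, {"species", "profile", "amplitude", "period", "phase", "baseline"},
            "input",
        )
        inputs.append(
            InputSpec(
                species=_species(d["species"], "input"),
                profile=d.get("profile", "constant"),
                amplitude=float(d.get("amplitude", 0.0)),
                period=float(d.get("period", 0.0)),
                phase=float(d.get("phase", 0.0)),
                baseline=float(d.get("baseline", 0.0)),
            )
        )
    genes = []
    for d in doc.get("genes") or []:
        _check_keys(
            d,
            {
                "product", "logic", "nu", "delta", "bindings",
                "rate_limiting_betas", "fixed_delay_steps", "initial_level",
                "initial_state",
            },
            "gene",
        )
        bindings = []
        for b in d.get("bindings") or []:
            _check_keys(b, {"tf", "lambda0", "mu", "role"}, "binding")
            bindings.append(
                TFBindingSpec(
                    tf=_species(b["tf"], "gene_product"),
                    lambda0=float(b["lambda0"]),
                    mu=float(b["mu"]),
                    role=b.get("role", "activator"),
                )
            )
        genes.append(
            GeneSpec(
                product=_species(d["product"], "gene_product"),
                logic=d.get("logic", "single"),
                nu=float(d["nu"]),
                delta=float(d["delta"]),
                bindings=tuple(bindings),
                rate_limiting_betas=tuple(
                    float(x) for x in d.get("rate_limiting_betas") or []
                ),
                fixed_delay_steps=int(d.get("fixed_delay_steps", 0)),
                initial_level=float(d.get("initial_level", 0.0)),
                initial_state=d.get("initial_state", "off"),
            )
        )
    rxns = []
    for d in doc.get("reactions") or []:
        _check_keys(
            d,
            {"kind", "substrates", "complex", "lambda", "mu", "deltas",
             "enzyme", "product", "nu", "product_initial"},
            "reaction",
        )
        rxns.append(
            ReactionSpec(
                kind=d["kind"],
                substrates=tuple(
                    _species(s, "gene_product") for s in d.get("substrates") or []
                ),
                complex=_species(d["complex"], "complex"),
                lam=float(d["lambda"]),
                mu=float(d["mu"]),
                enzyme=_species(d["enzyme"], "input") if d.get("enzyme") else None,
                product=(
                    _species(d["product"], "reaction_product")
                    if d.get("product")
                    else None
                ),
                nu=float(d.get("nu", 0.0)),
                deltas=tuple(float(x) for x in d.get("deltas") or []),
                product_initial=float(d.get("product_initial", 0.0)),
            )
        )
    return NetworkSpec(inputs=tuple(inputs), genes=tuple(genes), reactions=tuple(rxns))


def write_network(spec: NetworkSpec, path=None) -> str:
    """Serialize to canonical YAML; write to ``path`` if given, return the text."""
    text = yaml.safe_dump(
        network_to_dict(spec), sort_keys=False, default_flow_style=False
    )
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_network(source) -> NetworkSpec:
    """Read a network definition from a path or YAML string."""
    if isinstance(source, str) and "\n" in source:
        doc = yaml.safe_load(io.StringIO(source))
    else:
        with open(source) as fh:
            doc = yaml.safe_load(fh)
    return network_from_dict(doc)
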