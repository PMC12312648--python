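"""Network definition files (YAML or JSON).

The on-disk format mirrors the spec dataclasses field-for-field:

.. code-block:: yaml

    species:
      - {name: A, K: 1.0, x0: 1.0, kind: chemostat_amount}
      - {name: C, K: 2.0, x0: 0.0}
    reactions:
      - name: r1
        rate_param: 1.0
        forward_stoich: {A: 1, B: 1}
        reverse_stoich: {C: 1}
        law: mass_action

Round-trips are deterministic: load -> save -> load yields an identical
model.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import yaml

from .errors import ConfigurationError
from .network import NetworkSpec, ReactionSpec, SpeciesSpec


def network_to_dict(net: NetworkSpec) -> dict:
    species = []
    for s in net.species:
        rec = {"name": s.name, "K": s.K, "x0": s.x0, "kind": s.kind}
        if s.mu_clamp is not None:
            rec["mu_clamp"] = s.mu_clamp
        species.append(rec)
    reactions = []
    for r in net.reactions:
        rec = {
            "name": r.name,
            "rate_param": r.rate_param,
            "forward_stoich": {k: int(v) for k, v in r.forward_stoich.items()},
            "reverse_stoich": {k: int(v) for k, v in r.reverse_stoich.items()},
            "law": r.law,
        }
        if r.law_params:
            rec["law_params"] = dict(r.law_params)
        reactions.append(rec)
    return {"species": species, "reactions": reactions}


def network_from_dict(data: dict) -> NetworkSpec:
    try:
        species = [SpeciesSpec(**rec) for rec in data["species"]]
        reactions = [ReactionSpec(**rec) for rec in data["reactions"]]
    except (KeyError, TypeError) as exc:
        raise ConfigurationError(f"malformed network definition: {exc}") from exc
    return NetworkSpec(species, reactions)


def save_network(net: NetworkSpec, path: Union[str, Path]) -> None:
    path = Path(path)
    data = network_to_dict(net)
    if path.suffix in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    elif path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2))
    else:
        raise ConfigurationError(f"unknown model file extension {path.suffix!r}")


def load_network(path: Union[str, Path]) -> NetworkSpec:
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        data = yaml.safe_load(text)
    elif path.suffix == ".json":
        data = json.loads(text)
    else:
        raise ConfigurationError(f"unknown model file extension {path.suffix!r}")
    return network_from_dict(data)
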