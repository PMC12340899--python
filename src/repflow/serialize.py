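"""Model checkpoints: a single ``.npz`` container holding a JSON header
(configs, layout, training history) plus flat parameter vectors.
"""

from __future__ import annotations

import dataclasses
import json
import numpy as np

from .cfr import CFRHyperparams, Stage0CFR
from .flows import ConditionalFlow, FlowHyperparams, RepFlowCFR
from .nn import get_params_vector, set_params_vector


def _stage0_state(model: Stage0CFR) -> dict:
    header = {
        "hp": dataclasses.asdict(model.hp),
        "n_dynamic": model.n_dynamic,
        "n_static": model.n_static,
        "history": model.history,
    }
    arrays = {"params": get_params_vector(model.parameters)}
    if model._scaler is not None:
        arrays["scaler_mu"], arrays["scaler_sd"] = model._scaler
    return {"header": header, "arrays": arrays}


def _stage0_restore(header: dict, arrays: dict) -> Stage0CFR:
    model = Stage0CFR(header["n_dynamic"], header["n_static"],
                      CFRHyperparams(**header["hp"]))
    set_params_vector(model.parameters, arrays["params"])
    if "scaler_mu" in arrays:
        model._scaler = (arrays["scaler_mu"], arrays["scaler_sd"])
    model.history = header.get("history", [])
    return model


def _flow_state(flow: ConditionalFlow) -> dict:
    header = {
        "hp": dataclasses.asdict(flow.hp),
        "context_dim": flow.context_dim,
        "frozen": flow.frozen,
        "conditioned_on_treatment": getattr(flow, "conditioned_on_treatment",
                                            False),
        "history": flow.history,
    }
    arrays = {"params": get_params_vector(flow.parameters)}
    if flow._scaler is not None:
        arrays["scaler_mu"], arrays["scaler_sd"] = flow._scaler
    return {"header": header, "arrays": arrays}


def _flow_restore(header: dict, arrays: dict) -> ConditionalFlow:
    flow = ConditionalFlow(header["context_dim"], FlowHyperparams(**header["hp"]))
    set_params_vector(flow.parameters, arrays["params"])
    if "scaler_mu" in arrays:
        flow._scaler = (arrays["scaler_mu"], arrays["scaler_sd"])
    flow.conditioned_on_treatment = header["conditioned_on_treatment"]
    flow.history = header.get("history", [])
    if header["frozen"]:
        flow.freeze()
    return flow


def save_model(model: RepFlowCFR, path) -> None:
    parts = {"condition_stage2_on_treatment": model.condition_stage2_on_treatment}
    arrays = {}
    for name, state in (("stage0", _stage0_state(model.stage0)),
                        ("stage1", _flow_state(model.stage1)),
                        ("stage2", _flow_state(model.stage2))):
        parts[name] = state["header"]
        for k, v in state["arrays"].items():
            arrays[f"{name}__{k}"] = v
    np.savez(path, header=json.dumps(parts), **arrays)


def load_model(path) -> RepFlowCFR:
    with np.load(path, allow_pickle=False) as z:
        parts = json.loads(str(z["header"]))
        arrays = {k: z[k] for k in z.files if k != "header"}

    def sub(name):
        return {k.split("__", 1)[1]: v for k, v in arrays.items()
                if k.startswith(name + "__")}

    model = RepFlowCFR(
        hp_cfr=CFRHyperparams(**parts["stage0"]["hp"]),
        hp_flow=FlowHyperparams(**parts["stage1"]["hp"]),
        condition_stage2_on_treatment=parts["condition_stage2_on_treatment"])
    model.stage0 = _stage0_restore(parts["stage0"], sub("stage0"))
    model.stage1 = _flow_restore(parts["stage1"], sub("stage1"))
    model.stage2 = _flow_restore(parts["stage2"], sub("stage2"))
    return model


def save_stage0(model: Stage0CFR, path) -> None:
    state = _stage0_state(model)
    np.savez(path, header=json.dumps(state["header"]), **state["arrays"])


def load_stage0(path) -> Stage0CFR:
    with np.load(path, allow_pickle=False) as z:
        header = json.loads(str(z["header"]))
        arrays = {k: z[k] for k in z.files if k != "header"}
    return _stage0_restore(header, arrays)
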