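"""Configuration handling: YAML/JSON model configs, overrides, provenance.

A config file carries four blocks:

``model``
    Scalar fields of :class:`~aclcea.tree.ModelParams` except the two arm
    distributions.
``distributions``
    Per-arm activity-class counts (exact) or proportions.
``utilities``
    Per-class ``{mean, sd}`` blocks (the transformation key).
``psa``
    ``n_iterations`` and ``seed`` defaults, optional ``wtp_max``/``wtp_step``.

An optional ``calibration`` block records the published aggregates the
shipped residual costs and utility key were derived from, so both can be
recomputed from scratch (see :func:`calibrated_params_from_config` and
:func:`refit_utilities_from_config`).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources
from pathlib import Path
from typing import Any, Mapping

import yaml

from .evidence import CLASSES, ActivityClass, ActivityDistribution
from .tree import ModelParams, calibrate_residuals, replace_params
from .utilities import EffectTargets, FitResult, UtilityKey, fit_utilities

__all__ = [
    "load_config",
    "baseline_config",
    "baseline_config_path",
    "params_from_config",
    "key_from_config",
    "psa_defaults_from_config",
    "calibrated_params_from_config",
    "refit_utilities_from_config",
    "apply_overrides",
    "config_hash",
    "packaged_data_path",
]

_SCALAR_MODEL_FIELDS = {
    "p_fail": float,
    "p_crossover": float,
    "p_seq_operative": float,
    "p_seq_conservative": float,
    "split_oa_operative": float,
    "split_oa_conservative": float,
    "cost_surgical": float,
    "cost_conservative": float,
    "cost_oa": float,
    "cost_meniscus": float,
    "residual_cost_operative": float,
    "residual_cost_conservative": float,
    "horizon_months": float,
    "sequelae_class": str,
}


def packaged_data_path(name: str) -> Path:
    """Filesystem path of a data file shipped inside the package."""
    return Path(resources.files("aclcea").joinpath("data", name))  # type: ignore[arg-type]


def baseline_config_path() -> Path:
    return packaged_data_path("baseline.yaml")


def load_config(path: str | Path) -> dict:
    """Load a YAML or JSON config file into a plain dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError(f"{path}: config root must be a mapping")
    return data


def baseline_config() -> dict:
    return load_config(baseline_config_path())


def _distribution_from_block(block: Mapping[str, Any]) -> ActivityDistribution:
    if "counts" in block:
        counts = {ActivityClass.from_label(k): float(v) for k, v in block["counts"].items()}
        return ActivityDistribution.from_counts(counts)
    if "proportions" in block:
        props = {ActivityClass.from_label(k): float(v) for k, v in block["proportions"].items()}
        return ActivityDistribution.from_counts(props)
    raise ValueError("distribution block needs 'counts' or 'proportions'")


def params_from_config(config: Mapping[str, Any]) -> ModelParams:
    model = dict(config.get("model", {}))
    dists = config.get("distributions", {})
    for arm in ("operative", "conservative"):
        if arm not in dists:
            raise ValueError(f"config missing distributions.{arm}")
    kwargs: dict[str, Any] = {}
    for name, caster in _SCALAR_MODEL_FIELDS.items():
        if name in model:
            kwargs[name] = caster(model.pop(name))
    if model:
        raise ValueError(f"unknown model config fields: {sorted(model)}")
    if "sequelae_class" in kwargs:
        kwargs["sequelae_class"] = ActivityClass.from_label(kwargs["sequelae_class"])
    return ModelParams(
        dist_operative=_distribution_from_block(dists["operative"]),
        dist_conservative=_distribution_from_block(dists["conservative"]),
        **kwargs,
    )


def key_from_config(config: Mapping[str, Any]) -> UtilityKey:
    block = config.get("utilities")
    if not block:
        raise ValueError("config missing utilities block")
    means = {}
    sds = {}
    for label, entry in block.items():
        c = ActivityClass.from_label(label)
        means[c] = float(entry["mean"])
        sds[c] = float(entry.get("sd", 0.0))
    return UtilityKey(means=means, sds=sds)


def psa_defaults_from_config(config: Mapping[str, Any]) -> dict:
    block = dict(config.get("psa", {}))
    return {
        "n_iterations": int(block.get("n_iterations", 10_000)),
        "seed": int(block.get("seed", 0)),
        "wtp_max": float(block.get("wtp_max", 100_000.0)),
        "wtp_step": float(block.get("wtp_step", 1000.0)),
    }


def calibrated_params_from_config(config: Mapping[str, Any]) -> ModelParams:
    """Model parameters with residual costs recomputed from the calibration
    anchors rather than taken from the stored values.

    Requires a ``calibration`` block with ``target_cost_operative`` and
    ``target_cost_conservative``.
    """
    cal = config.get("calibration")
    if not cal:
        raise ValueError("config has no calibration block")
    params = params_from_config(config)
    return calibrate_residuals(
        params,
        float(cal["target_cost_operative"]),
        float(cal["target_cost_conservative"]),
    )


def refit_utilities_from_config(config: Mapping[str, Any]) -> FitResult:
    """Re-run the utility calibration from the calibration anchors.

    Uses the published arm effects (cost / cost-effectiveness ratio) as
    targets and, when present, the published worst-case ICER to pin the
    no-sequelae incremental effect.
    """
    cal = config.get("calibration")
    if not cal:
        raise ValueError("config has no calibration block")
    params = calibrated_params_from_config(config)
    targets = EffectTargets(
        target_effect_operative=float(cal["target_cost_operative"])
        / float(cal["target_ce_ratio_operative"]),
        target_effect_conservative=float(cal["target_cost_conservative"])
        / float(cal["target_ce_ratio_conservative"]),
    )
    worst_case_incr_effect = None
    if "target_worst_case_icer" in cal:
        # the worst-case incremental cost depends only on cost parameters
        from .tree import STRATEGIES, run_strategies
        from .utilities import UtilityKey as _Key

        wc = replace_params(params, p_seq_operative=0.0, p_seq_conservative=0.0)
        flat = _Key(means={c: 0.5 for c in CLASSES})
        by_name = {r.strategy: r.expected_cost for r in run_strategies(wc, flat)}
        wc_incr_cost = by_name["reconstruction"] - by_name["conservative"]
        worst_case_incr_effect = wc_incr_cost / float(cal["target_worst_case_icer"])
    sds = {c: key_from_config(config).sd(c) for c in CLASSES} if "utilities" in config else None
    return fit_utilities(
        targets, params, worst_case_incr_effect=worst_case_incr_effect, sds=sds
    )


def apply_overrides(params: ModelParams, overrides: Mapping[str, str]) -> ModelParams:
    """Apply ``name=value`` CLI overrides to scalar model parameters."""
    changes: dict[str, Any] = {}
    for name, raw in overrides.items():
        if name not in _SCALAR_MODEL_FIELDS:
            raise ValueError(
                f"unknown model parameter {name!r}; valid: {sorted(_SCALAR_MODEL_FIELDS)}"
            )
        caster = _SCALAR_MODEL_FIELDS[name]
        value: Any = caster(raw)
        if name == "sequelae_class":
            value = ActivityClass.from_label(value)
        changes[name] = value
    return replace_params(params, **changes)


def config_hash(config: Mapping[str, Any]) -> str:
    """Stable SHA-256 of a config's canonical JSON form (first 16 hex chars)."""
    canonical = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canonical.encode()).hexdigest()[:16]
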