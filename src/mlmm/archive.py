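"""Trained-model persistence.

One HDF5 container holds every array of the embedding model (per-element
GPR property models, the optional flexible k_α model) plus a JSON metadata
block carrying descriptor settings, the element vocabulary, k_Z ratios,
hyperparameters and a format version.
"""

from __future__ import annotations

import json

import h5py
import numpy as np

from .descriptors import DescriptorSettings
from .gpr import PerElementGPR, SparseGPRModel
from .static import StaticModel
from .thole import PolarizabilityModel

FORMAT_VERSION = 1


def _write_gpr(group, model: SparseGPRModel):
    for name, arr in model.to_arrays().items():
        group.create_dataset(name, data=np.asarray(arr))


def _read_gpr(group) -> SparseGPRModel:
    return SparseGPRModel.from_arrays(
        {name: group[name][()] for name in group}
    )


def save_model(path, static_model: StaticModel,
               pol_model: PolarizabilityModel | None = None) -> None:
    with h5py.File(path, "w") as f:
        meta = {
            "format_version": FORMAT_VERSION,
            "descriptor_settings": static_model.settings.to_dict(),
            "hardness_rule": static_model.hardness_rule,
        }
        for name, per_el in (
            ("electronegativity", static_model.electronegativity_model),
            ("width", static_model.width_model),
            ("volume", static_model.volume_model),
        ):
            g = f.create_group(f"static/{name}")
            for el, m in per_el.models.items():
                _write_gpr(g.create_group(el), m)
        if pol_model is not None:
            meta["polarizability"] = {
                "k_z": pol_model.k_z,
                "mode": pol_model.mode,
                "thole_damping_a": pol_model.thole_damping_a,
            }
            if pol_model.k_alpha_model is not None:
                _write_gpr(
                    f.create_group("polarizability/k_alpha"),
                    pol_model.k_alpha_model,
                )
        f.attrs["metadata"] = json.dumps(meta)


def load_model(path):
    """Returns ``(StaticModel, PolarizabilityModel | None)``."""
    with h5py.File(path, "r") as f:
        meta = json.loads(f.attrs["metadata"])
        if meta["format_version"] > FORMAT_VERSION:
            raise ValueError(
                f"model archive format {meta['format_version']} is newer "
                f"than supported ({FORMAT_VERSION})"
            )
        settings = DescriptorSettings.from_dict(meta["descriptor_settings"])
        per_els = {}
        for name in ("electronegativity", "width", "volume"):
            g = f[f"static/{name}"]
            per_els[name] = PerElementGPR(
                {el: _read_gpr(g[el]) for el in g}
            )
        static_model = StaticModel(
            per_els["electronegativity"], per_els["width"],
            per_els["volume"], settings,
            hardness_rule=meta.get("hardness_rule", "inverse_width"),
        )
        pol_model = None
        if "polarizability" in meta:
            p = meta["polarizability"]
            k_alpha = None
            if "polarizability/k_alpha" in f:
                k_alpha = _read_gpr(f["polarizability/k_alpha"])
            pol_model = PolarizabilityModel(
                k_z=dict(p["k_z"]),
                mode=p["mode"],
                k_alpha_model=k_alpha,
                settings=settings,
                thole_damping_a=p["thole_damping_a"],
            )
    return static_model, pol_model
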