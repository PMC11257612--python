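"""Parameter-set loading (JSON/YAML) and the bundled published medians."""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path
from typing import Optional, Tuple

import yaml

from .models import Environment, KinasePhenotype, SwimmingPhenotype

__all__ = ["load_params_file", "published_params", "load_published"]


def load_params_file(path) -> dict:
    """Read a JSON or YAML parameter file into a dict."""
    path = Path(path)
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def published_params() -> dict:
    """The bundled population-median parameter sets."""
    text = resources.files("chemoinfo").joinpath("params_published.yaml").read_text()
    return yaml.safe_load(text)


def _background_key(c0: float, backgrounds: dict) -> str:
    for key in backgrounds:
        if abs(float(key) - c0) <= 1e-9 * max(1.0, abs(c0)):
            return key
    raise KeyError(
        f"no published parameters for c0={c0} uM "
        f"(available: {sorted(backgrounds)})"
    )


def load_published(
    c0: float = 1.0,
    g: float = 0.0,
    params: Optional[dict] = None,
    generation: bool = False,
) -> Tuple[SwimmingPhenotype, KinasePhenotype, Environment]:
    """Phenotypes and environment at a measured background concentration.

    ``g`` is in um^-1 (use ``Environment.from_g_mm`` semantics upstream for
    mm^-1 interfaces).  ``generation=True`` returns the kinase phenotype used
    by the synthetic-data generators, which carries the measured fast
    response time tau_1 (the information calculations use tau_1 = 0).
    """
    p = params if params is not None else published_params()
    bg = p["backgrounds"][_background_key(c0, p["backgrounds"])]
    gen = p.get("generator", {})
    env = Environment(
        c0=c0, g=g, k_D=p["environment"]["k_D"],
        D_ligand=p["environment"]["D_ligand"],
        l_sensor=p["environment"]["l_sensor"],
    )
    swim = SwimmingPhenotype(
        sigma_v2=bg["sigma_v2"], tau_v=bg["tau_v"],
        speed=gen.get("speed", 18.6), p_run=gen.get("p_run", 0.85),
        mean_run=gen.get("mean_run", 0.86),
        mean_tumble=gen.get("mean_tumble", 0.15),
        persistence=gen.get("persistence", 0.33),
        d_rot=gen.get("d_rot", 0.062),
    )
    tau_1 = gen.get("tau_1", 0.5) if generation else bg.get("tau_1", 0.0)
    kin = KinasePhenotype(
        G_r=bg["G_r_kD"] / env.k_D, tau_1=tau_1,
        tau_2=bg["tau_2"], D_n=bg["D_n"], tau_n=bg["tau_n"],
        a0=gen.get("a0", 0.3), G_inf=p["mwc"]["G_inf"], K_i=p["mwc"]["K_i"],
    )
    return swim, kin, env
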