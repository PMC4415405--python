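import numpy as np
import pytest

from colonydiff import (
    default_line,
    estimate_din_dout,
    extract_profile,
    locate_colony,
    relative_profile,
    simulate_scenario,
)


@pytest.fixture(scope="session")
def paper_run():
    """One paper-like dextran fixture (stack + ground truth), reused across
    test modules to keep the suite fast."""
    return simulate_scenario("dextran10-LD61-like", seed=0)


@pytest.fixture(scope="session")
def paper_analysis(paper_run):
    """Full pipeline products for the paper-like fixture."""
    stack, truth = paper_run
    cfg = truth.config
    mask = locate_colony(stack.frames[0, 0], stack.pixel_size)
    series = extract_profile(stack, default_line(mask, stack.frames.shape[-2:]))
    fit = estimate_din_dout(
        series,
        mask,
        fit_time=1800.0,
        background=cfg.background_level,
        x_offset=cfg.window_offset,
    )
    return {"stack": stack, "truth": truth, "mask": mask, "series": series, "fit": fit}


def analyze_scenario(scenario: str, seeds, fit_time=1800.0, plateau_time=7200.0):
    """Run the simulate -> locate -> profile -> fit pipeline over seeds.

    The 1-D field is seed-independent, so it is solved once per scenario
    and only rendering, localization and fitting are repeated.
    """
    from colonydiff.simulate import (
        default_geometry,
        render_stack,
        scenario_config,
        solve_diffusion,
    )

    cfg0 = scenario_config(scenario, seed=0)
    field = solve_diffusion(cfg0)
    out = {
        "ratio": [], "r2_out": [], "r2_in": [], "plateau": [],
        "center_err_px": [], "radius_rel_err": [], "truth_ratio": cfg0.d_in / cfg0.d_out,
    }
    for seed in seeds:
        cfg = scenario_config(scenario, seed=int(seed))
        stack, truth = render_stack(field, default_geometry(cfg), cfg)
        mask = locate_colony(stack.frames[0, 0], stack.pixel_size)
        geo = truth.geometry
        ps = cfg.pixel_size
        out["center_err_px"].append(
            float(np.hypot(mask.center[0] - geo.center[1] / ps,
                           mask.center[1] - geo.center[0] / ps))
        )
        out["radius_rel_err"].append(
            abs(mask.radius - geo.radius / ps) / (geo.radius / ps)
        )
        series = extract_profile(stack, default_line(mask, stack.frames.shape[-2:]))
        fit = estimate_din_dout(
            series, mask, fit_time=fit_time,
            background=cfg.background_level, x_offset=cfg.window_offset,
        )
        out["ratio"].append(fit.ratio_in_out)
        out["r2_out"].append(fit.fit_out.r2)
        out["r2_in"].append(fit.fit_in.r2)
        rel = relative_profile(series, mask, plateau_time, background=cfg.background_level)
        out["plateau"].append(rel.colony_mean(mask, buffer_um=3 * ps))
    return {k: (np.asarray(v) if isinstance(v, list) else v) for k, v in out.items()}


@pytest.fixture(scope="session")
def paperlike_ensemble():
    """Pipeline metrics over 20 seeded paper-like fixtures."""
    return analyze_scenario("dextran10-LD61-like", range(20))
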