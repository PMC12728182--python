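"""Staged analysis pipelines: CEST (noise -> masks -> residue fits ->
assignment -> global 3-site -> global 4-site -> model comparison ->
bootstrap) and ITC (per-temperature one-site fits -> thermodynamic table ->
entropy decomposition).

Each stage is a plain function over in-memory objects; the two ``run_*``
entry points orchestrate them, write JSON summaries and delimited tables,
and log seeds and timings for provenance.  No stage mutates its inputs on
disk.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import analysis as an
from . import itc as itcmod
from .exceptions import InvalidInputError
from .exchange import apparent_kd, bound_fraction, partition_populations

logger = logging.getLogger("foldbind")

__all__ = [
    "residue_dw_inits",
    "staged_cest_fit",
    "run_cest_pipeline",
    "run_thermo_pipeline",
]


def _alias_set(dw: float, window_ppm: float | None,
               max_abs: float = 8.0) -> list:
    """All aliases of a shift difference compatible with one profile."""
    if window_ppm is None:
        return [dw]
    k_max = int(np.ceil(max_abs / window_ppm)) + 1
    return [dw + k * window_ppm for k in range(-k_max, k_max + 1)
            if abs(dw + k * window_ppm) <= max_abs]


def residue_dw_inits(dataset: an.CestDataset,
                     depth_threshold: float = 4.0,
                     match_tol: float = 0.3) -> dict:
    """Initial dw_FB/dw_FC per residue from consensus dip picking.

    D-CEST dips are only defined modulo the spectral window, so each pick
    is expanded into its alias set; a candidate shift difference is
    retained when aliases from at least two different profiles (different
    windows, or the unaliased CW profile) agree within ``match_tol`` ppm —
    the true position is the unique value consistent across windows.
    Single-profile picks are kept only as a fallback when nothing reaches
    consensus.  The candidate nearest the major state seeds dw_FB, the
    farthest dw_FC.
    """
    inits = {}
    for rid in dataset.residue_ids:
        profs = dataset.profiles_for(rid)
        shift = dataset.residues[rid].shift_f
        entries = []  # (alias list, profile index)
        for idx, p in enumerate(profs):
            e = p.experiment
            window_ppm = (e.dante_window / e.larmor_15n
                          if e.scheme == "dante" else None)
            for pos in an.pick_dips(p, depth_threshold=depth_threshold,
                                    major_shift=shift):
                entries.append((_alias_set(pos - shift, window_ppm), idx))
        scored = []
        for aliases, idx in entries:
            for v in aliases:
                support = {
                    j for al, j in entries
                    if any(abs(a - v) <= match_tol for a in al)
                }
                scored.append((v, len(support)))
        scored.sort(key=lambda t: (-t[1], abs(t[0])))
        min_support = 2 if any(s >= 2 for _, s in scored) else 1
        accepted = []
        for v, s in scored:
            if s < min_support:
                continue
            if all(abs(v - a) > 2 * match_tol for a in accepted):
                accepted.append(v)
            if len(accepted) == 3:
                break
        dws = sorted(accepted, key=abs)
        if len(dws) >= 2:
            inits[rid] = {"dw_fb": dws[0], "dw_fc": dws[1]}
        elif len(dws) == 1:
            inits[rid] = {"dw_fb": dws[0], "dw_fc": dws[0]}
        else:
            inits[rid] = {"dw_fb": 0.0, "dw_fc": 0.0}
        inits[rid]["candidates"] = dws
    return inits


def _candidate_configs(cands: list) -> list:
    """Candidate (dw_FB, dw_FC) start configurations for one residue.

    Dip picking leaves three ambiguities the residue-specific fit must
    resolve: which dip is B and which is C, whether a single dip hides two
    overlapping states, and the alias sign of dips seen only in D-CEST
    windows.  Each plausible configuration seeds one local fit; the best
    chi-square wins.
    """
    if not cands:
        return [(0.0, 0.0)]
    configs = []
    d = cands[:3]
    if len(d) == 1:
        configs = [(d[0], d[0]), (-d[0], -d[0]), (d[0] / 2.0, d[0])]
    else:
        for i in range(len(d)):
            for j in range(len(d)):
                if i != j:
                    configs.append((d[i], d[j]))
        configs.append((d[0], d[0]))
        configs.append((-d[0], -d[0]))
    seen, out = set(), []
    for c in configs:
        key = (round(c[0], 2), round(c[1], 2))
        if key not in seen:
            seen.add(key)
            out.append(c)
    return out[:6]


def _dw_scan_starts(model, x_cur, rid, crib: bool, step: float = 0.8,
                    span: float = 7.2, top: int = 2) -> list:
    """Coarse 2-D chi-square scan over (dw_FB, dw_FC) for one residue.

    With the global exchange rates frozen, the residue's chi-square surface
    over the two shift differences has well-separated basins (one per
    alias/assignment hypothesis); scanning it outright is cheap and immune
    to the ambiguities that defeat dip picking.  Returns the ``top``
    basin centres as start configurations.
    """
    grid = np.arange(-span, span + 1e-9, step)
    j_fb = j_fc = j_fa = None
    for j, p in enumerate(model.params):
        if p.rid != rid:
            continue
        j_fb = j if p.name == "dw_fb" else j_fb
        j_fc = j if p.name == "dw_fc" else j_fc
        j_fa = j if p.name == "dw_fa" else j_fa
    nodes = []
    x = x_cur.copy()
    for fb in grid:
        for fc in grid:
            x[j_fb], x[j_fc] = fb, fc
            if j_fa is not None:
                x[j_fa] = fb if crib else 0.0
            nodes.append((model.chi2(x), fb, fc))
    nodes.sort()
    starts = []
    for chi2, fb, fc in nodes:
        if all(abs(fb - a) + abs(fc - b) > 1.2 for a, b in starts):
            starts.append((fb, fc))
        if len(starts) == top:
            break
    return starts


def _refine_residue_assignments(
    dataset: an.CestDataset,
    spec: an.FitSpec,
    result: an.GlobalFitResult,
    candidates: dict,
    min_drop: float = 2.0,
    max_nfev: int = 80,
) -> tuple[dict, bool]:
    """Per-residue re-assignment pass under fixed global rates.

    A global fit can park single residues in locally optimal but wrong
    minor-state assignments (swapped B/C, wrong alias sign) without the
    global parameters being able to pull them out.  With the exchange
    parameters frozen at the global optimum, each residue is refit from
    every candidate (dw_FB, dw_FC) configuration; a configuration is
    adopted when it improves that residue's chi-square by ``min_drop``.
    Returns the (possibly updated) residue parameter map and whether any
    residue moved.
    """
    updated = {rid: dict(p) for rid, p in result.residue_params.items()}
    gfixed = {k: result.global_params[k]
              for k in an.GLOBAL_PARAMS[spec.model]}
    improved = False
    # only residues whose misfit stands out against the typical per-point
    # residual need re-assignment; scanning the rest is wasted work
    per_point = {}
    model_full = an._CestModel(dataset, replace(
        spec, fixed_globals=gfixed, residue_init=updated))
    resid = model_full.residuals(model_full.x0())
    for prof, sl in zip(model_full.profiles, model_full.row_slices):
        chi, npts = float((resid[sl] ** 2).sum()), sl.stop - sl.start
        c, n = per_point.get(prof.residue_id, (0.0, 0))
        per_point[prof.residue_id] = (c + chi, n + npts)
    rates = {rid: c / max(n, 1) for rid, (c, n) in per_point.items()}
    typical = float(np.median(list(rates.values())))
    suspects = [rid for rid, r in rates.items()
                if r > max(2.0 * typical, typical + 0.05)]
    for rid in suspects:
        sub = dataset.subset([rid])
        spec_r = replace(spec, fixed_globals=gfixed,
                         excluded_residues=frozenset(),
                         residue_init={rid: updated[rid]})
        model = an._CestModel(sub, spec_r)
        x_cur = model.x0()
        best_chi2 = model.chi2(x_cur)
        best_params = None
        cands = list(candidates.get(rid, []))
        extra = [v for v in (updated[rid]["dw_fb"], updated[rid]["dw_fc"])
                 if all(abs(v - c) > 0.3 for c in cands)]
        configs = _candidate_configs(cands + extra)
        configs += _dw_scan_starts(model, x_cur, rid,
                                   crib=rid in spec.crib_set)
        for dw_fb, dw_fc in configs:
            x0 = x_cur.copy()
            for j, p in enumerate(model.params):
                if p.name == "dw_fb":
                    x0[j] = dw_fb
                elif p.name == "dw_fc":
                    x0[j] = dw_fc
                elif p.name == "dw_fa":
                    x0[j] = dw_fb if rid in spec.crib_set else 0.0
            sol = model.fit(x0=x0, n_starts=1, max_nfev=max_nfev)
            chi2 = 2.0 * sol.cost
            if chi2 < best_chi2 - min_drop:
                best_chi2 = chi2
                _, per_res = model.unpack(sol.x)
                best_params = dict(per_res[rid])
        if best_params is not None:
            updated[rid] = best_params
            improved = True
            logger.info("residue %d re-assigned (chi2 -> %.1f)", rid,
                        best_chi2)
    return updated, improved


def _warm_spec(spec: an.FitSpec, result: an.GlobalFitResult,
               residue_params: dict | None = None, **kw) -> an.FitSpec:
    return replace(
        spec,
        global_init={k: result.global_params[k]
                     for k in an.GLOBAL_PARAMS[spec.model]},
        residue_init=residue_params or result.residue_params,
        **kw,
    )


def _collective_hypotheses(result: an.GlobalFitResult) -> list:
    """Joint discrete re-assignment hypotheses across residues.

    A single dip is explained equally well, residue by residue, with the
    intermediate B unshifted (dw_FB ~ 0) or co-shifted with the complex
    (dw_FB = dw_FC); the global rates take different values in the two
    interpretations, so individual residues cannot cross between them once
    a global fit has settled.  The hypotheses below move all degenerate
    residues at once and are accepted only if the global refit improves.
    """
    variants = []
    co_shifted = {rid: dict(p) for rid, p in result.residue_params.items()}
    changed = False
    for p in co_shifted.values():
        if abs(p["dw_fb"]) < 0.3 and abs(p["dw_fc"]) > 0.5:
            p["dw_fb"] = p["dw_fc"]
            changed = True
    if changed:
        variants.append(co_shifted)
    unshifted = {rid: dict(p) for rid, p in result.residue_params.items()}
    changed = False
    for p in unshifted.values():
        if abs(p["dw_fc"] - p["dw_fb"]) < 0.3 and abs(p["dw_fb"]) > 0.5:
            p["dw_fb"] = 0.0
            changed = True
    if changed:
        variants.append(unshifted)
    return variants


def _refit_with_refinement(
    dataset: an.CestDataset,
    spec: an.FitSpec,
    result: an.GlobalFitResult,
    candidates: dict,
    rng,
    max_rounds: int = 3,
    multistart: int = 0,
) -> an.GlobalFitResult:
    """Alternate residue re-assignment and warm-started global refits.

    Intermediate refits run at a relaxed tolerance; when ``multistart`` is
    set, rounds of rate-jittered restarts are interleaved so the global
    rate parameters can leave a basin that residue re-assignment alone
    cannot escape.  The returned result is polished at the strict tolerance.
    """
    for round_idx in range(max_rounds):
        moved = False
        for hyp in _collective_hypotheses(result):
            warm = _warm_spec(spec, result, hyp, ftol=1e-6, max_nfev=200)
            refit = an.fit_global(dataset, warm, rng=rng)
            if refit.chi2 < result.chi2 - 0.1:
                logger.info("refinement round %d: hypothesis %.1f -> %.1f",
                            round_idx, result.chi2, refit.chi2)
                result = refit
                moved = True
        new_params, improved = _refine_residue_assignments(
            dataset, spec, result, candidates
        )
        if improved:
            warm = _warm_spec(spec, result, new_params, ftol=1e-6,
                              max_nfev=200)
            refit = an.fit_global(dataset, warm, rng=rng)
            if refit.chi2 < result.chi2:
                logger.info("refinement round %d: re-assignment %.1f -> %.1f",
                            round_idx, result.chi2, refit.chi2)
                result = refit
                moved = True
        if multistart > 1 and not moved:
            warm = _warm_spec(spec, result, n_starts=multistart,
                              ftol=1e-6, max_nfev=150)
            restart = an.fit_global(dataset, warm, rng=rng)
            if restart.chi2 < result.chi2 - 0.1:
                logger.info("refinement round %d: restart %.1f -> %.1f",
                            round_idx, result.chi2, restart.chi2)
                result = restart
                moved = True
        if not moved:
            break
    # final polish at the strict tolerance
    polish = an.fit_global(
        dataset, _warm_spec(spec, result, ftol=1e-8, max_nfev=120), rng=rng
    )
    return polish if polish.chi2 < result.chi2 else result


def staged_cest_fit(
    dataset: an.CestDataset,
    crib_set=frozenset(),
    excluded_residues=frozenset(),
    r2b_eq_r2c=frozenset(),
    crib_range: tuple | None = None,
    run_assignment: bool = True,
    residue_n_starts: int = 3,
    seed: int | None = None,
    estimate_sigmas: bool = True,
) -> dict:
    """Run the staged CEST analysis and return all stage results.

    ``crib_set`` fixes the anchored residues of the 4-site model;
    ``crib_range`` instead searches for them.  Returns a dict with keys
    res3 (global 3-site), res4 (global 4-site), comparison, assignments,
    residue_fits, inits and timings.
    """
    rng = np.random.default_rng(seed)
    timings = {}
    t0 = time.perf_counter()
    if estimate_sigmas:
        dataset.apply_noise_estimates()
    dataset.apply_exclusion_masks()
    timings["noise_and_masks"] = time.perf_counter() - t0

    fit_rids = [r for r in dataset.residue_ids if r not in excluded_residues]

    t0 = time.perf_counter()
    inits = residue_dw_inits(dataset)
    residue_fits = {}
    for rid in fit_rids:
        best = None
        for dw_fb, dw_fc in _candidate_configs(inits[rid]["candidates"]):
            fit = an.fit_residue_3site(
                dataset, rid, residue_init={"dw_fb": dw_fb, "dw_fc": dw_fc},
                n_starts=1, rng=rng,
            )
            if best is None or fit.chi2 < best.chi2:
                best = fit
            if best.chi2 / max(best.n_points, 1) < 1.3:
                break  # already at the per-point residual floor
        residue_fits[rid] = best
    timings["residue_fits"] = time.perf_counter() - t0

    assignments = {}
    if run_assignment:
        t0 = time.perf_counter()
        for rid, rf in residue_fits.items():
            rp = rf.residue_params[rid]
            if abs(rp["dw_fb"]) > 0.1 and abs(rp["dw_fc"]) > 0.1:
                assignments[rid] = an.assign_minor_states(dataset, rid, rf,
                                                          rng=rng)
        timings["assignment"] = time.perf_counter() - t0

    # global 3-site, seeded from the medians of the residue-specific fits
    t0 = time.perf_counter()
    informative = [rid for rid in fit_rids
                   if abs(inits[rid]["dw_fb"]) > 0.1
                   or abs(inits[rid]["dw_fc"]) > 0.1] or fit_rids
    g3 = {k: float(np.median([residue_fits[rid].global_params[k]
                              for rid in informative]))
          for k in an.GLOBAL_PARAMS["3site"]}
    ri3 = {rid: dict(rf.residue_params[rid])
           for rid, rf in residue_fits.items()}
    spec3 = an.FitSpec(model="3site", global_init=g3, residue_init=ri3,
                       excluded_residues=excluded_residues,
                       r2b_eq_r2c=r2b_eq_r2c, ftol=1e-6, max_nfev=250)
    res3 = an.fit_global(dataset, spec3, rng=rng)
    cand_map = {rid: inits[rid]["candidates"] for rid in fit_rids}
    res3 = _refit_with_refinement(dataset, spec3, res3, cand_map, rng)
    timings["global_3site"] = time.perf_counter() - t0
    logger.info("global 3-site: chi2 = %.1f (%d points)", res3.chi2,
                res3.n_points)

    # global 4-site, warm-started from the 3-site solution
    t0 = time.perf_counter()
    ri4 = {rid: dict(p) for rid, p in res3.residue_params.items()}
    kex0 = res3.global_params["k_bc"] + res3.global_params["k_cb"]
    g4 = {"koff": res3.global_params["koff"], "kex_ab": kex0, "kex_bc": kex0,
          "keq_ab": 1.0,
          "keq_bc": res3.global_params["k_bc"] / res3.global_params["k_cb"]}
    spec4 = an.FitSpec(model="4site", crib_set=crib_set, global_init=g4,
                       residue_init=ri4, excluded_residues=excluded_residues,
                       r2b_eq_r2c=r2b_eq_r2c, ftol=1e-6, max_nfev=250)
    crib_search = None
    if crib_range is not None:
        warm = an.fit_global(dataset, spec4, rng=rng)
        crib_search = an.search_crib_boundary(dataset, spec4, crib_range,
                                              warm_start=warm, rng=rng)
        res4 = crib_search.best_fit
        spec4 = replace(spec4, crib_set=crib_search.best_set)
    else:
        for rid in crib_set:
            if rid in ri4:
                ri4[rid]["dw_fa"] = ri4[rid]["dw_fb"]
        res4 = an.fit_global(dataset, spec4, rng=rng)
        res4 = _refit_with_refinement(dataset, spec4, res4, cand_map, rng,
                                      multistart=3)
    timings["global_4site"] = time.perf_counter() - t0
    logger.info("global 4-site: chi2 = %.1f", res4.chi2)

    comparison = an.compare_models(res3, res4)
    return {"res3": res3, "res4": res4, "comparison": comparison,
            "assignments": assignments, "residue_fits": residue_fits,
            "inits": inits, "crib_search": crib_search, "timings": timings,
            "seed": seed}


def _result_record(res: an.GlobalFitResult) -> dict:
    rec = {
        "model": res.model,
        "global_params": {k: float(v) for k, v in res.global_params.items()},
        "global_sigmas": ({k: float(v) for k, v in res.global_sigmas.items()}
                          if res.global_sigmas else None),
        "chi2": res.chi2, "n_points": res.n_points, "n_free": res.n_free,
        "success": res.success,
    }
    return rec


def run_cest_pipeline(
    dataset: an.CestDataset,
    outdir,
    crib_set=frozenset(),
    crib_range: tuple | None = None,
    excluded_residues=frozenset(),
    r2b_eq_r2c=frozenset(),
    model: str = "4site",
    bootstrap_n: int = 0,
    seed: int | None = None,
) -> dict:
    """Full CEST pipeline with provenance; writes summary JSON and tables."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()
    staged = staged_cest_fit(
        dataset, crib_set=crib_set, crib_range=crib_range,
        excluded_residues=excluded_residues, r2b_eq_r2c=r2b_eq_r2c,
        seed=seed,
    )
    res3, res4, comparison = staged["res3"], staged["res4"], staged["comparison"]
    preferred = comparison.preferred if model == "4site" else "3site"
    best = res4 if preferred == "4site" else res3

    boot = None
    if bootstrap_n and best.spec is not None:
        boot = an.bootstrap_global(dataset, best.spec, best, n=bootstrap_n,
                                   seed=seed)

    scheme = an.scheme_from_globals(best.model, best.global_params)
    summary = {
        "seed": seed,
        "constraint": {"Kd_uM": dataset.composition.kd,
                       "P0_uM": dataset.composition.p0,
                       "R0_uM": dataset.composition.r0,
                       "bound_fraction": bound_fraction(dataset.composition)},
        "fit_3site": _result_record(res3),
        "fit_4site": _result_record(res4) if model == "4site" else None,
        "model_comparison": ({"F": comparison.f_stat, "p": comparison.p_value,
                              "preferred_model": comparison.preferred}
                             if model == "4site" else None),
        "preferred_model": preferred,
        "derived": {
            "apparent_Kd_uM": apparent_kd(replace(
                scheme, kon=an.derive_kon(scheme, dataset.composition))),
            "kon_M_s": an.derive_kon(scheme, dataset.composition),
        },
        "bootstrap": ({"n": boot.n_replicates, "dropped": boot.n_dropped,
                       "ci68": {k: list(v) for k, v in boot.ci68.items()},
                       "seed": boot.seed} if boot else None),
        "timings_s": staged["timings"],
        "total_s": time.perf_counter() - t_start,
    }
    (outdir / "cest_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    rows = [{"residue_id": rid, **{k: float(v) for k, v in p.items()}}
            for rid, p in best.residue_params.items()]
    pd.DataFrame(rows).to_csv(outdir / "cest_residue_params.tsv", sep="\t",
                              index=False, float_format="%.6g")
    _write_fitted_curves(dataset, best, outdir / "cest_fitted_curves.tsv")
    return summary


def _write_fitted_curves(dataset, result, path) -> None:
    model = an._CestModel(dataset, result.spec)
    x = model.x_from_result(result)
    g, per_res = model.unpack(x)
    scheme = an.scheme_from_globals(result.model, g)
    pops = partition_populations(model.total_bound, scheme)
    from .forward import _profile_intensities
    rows = []
    for prof in model.profiles:
        spin = model._spin(prof.residue_id, per_res[prof.residue_id])
        fit = _profile_intensities(spin, scheme, pops, prof.experiment)
        for off, obs, pred, used in zip(prof.offsets, prof.intensities, fit,
                                        prof.mask):
            rows.append({"residue_id": prof.residue_id,
                         "B1_Hz": prof.experiment.b1, "offset_Hz": off,
                         "observed": obs, "fitted": pred,
                         "included": int(used)})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False,
                              float_format="%.6g")


def run_thermo_pipeline(
    series: list,
    outdir,
    t_extrapolate: float = 298.15,
    seed: int | None = None,
) -> dict:
    """ITC pipeline: per-temperature fits, dCp, T_S, Kd extrapolation and
    the Spolar-Record decomposition with folded-residue count."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    temps = sorted({s.temperature for s in series})
    if len(temps) < 3:
        raise InvalidInputError(
            "thermo pipeline needs titrations at >= 3 temperatures"
        )
    fits = []
    for s in series:
        fits.append((s.temperature, itcmod.fit_one_site(s)))
    # average duplicates per temperature at the parameter level
    by_t = {}
    for t, f in fits:
        by_t.setdefault(t, []).append(f)
    merged = {
        t: itcmod.OneSiteFit(
            n=float(np.mean([f.n for f in fs])),
            kd=float(np.mean([f.kd for f in fs])),
            dh=float(np.mean([f.dh for f in fs])),
        )
        for t, fs in by_t.items()
    }
    table = itcmod.ThermoTable.from_fits(merged)
    dcp = itcmod.heat_capacity(table)
    t_s = itcmod.iso_entropic_temp(table)
    kd_x = itcmod.extrapolate_kd(table, t_extrapolate)
    decomp = itcmod.spolar_record(dcp, t_s)
    check = abs(decomp.ds_total) < 1e-9
    summary = {
        "seed": seed,
        "temperatures_K": temps,
        "per_temperature": table.frame.to_dict(orient="records"),
        "dCp_kJ_mol_K": dcp,
        "T_S_K": t_s,
        "Kd_extrapolated_uM": kd_x,
        "T_extrapolate_K": t_extrapolate,
        "decomposition": {
            "dS_conformational_J": decomp.ds_conformational,
            "dS_desolvation_J": decomp.ds_desolvation,
            "dS_rt_J": decomp.ds_rt,
            "dS_total_at_TS_J": decomp.ds_total,
            "total_vanishes_at_TS": bool(check),
            "folded_residues": decomp.folded_residues,
        },
    }
    (outdir / "thermo_summary.json").write_text(
        json.dumps(summary, indent=2, default=float))
    table.frame.to_csv(outdir / "thermo_table.tsv", sep="\t", index=False,
                       float_format="%.6g")
    return summary
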