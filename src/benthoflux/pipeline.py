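"""The full inference chain: raw tables in, per-location flux report out.

Stage order mirrors the field workflow: sediment properties first (porosity
feeds every diffusivity), then chamber totals, microprofile DOU, pore-water
diffusive fluxes, community metrics, and finally the carbon budget. Any stage
failure aborts with the stage name and the offending input identifier; every
flux that a QC rule would exclude is still reported, with its flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .budget import budget as _budget
from . import chamber as chamber_mod
from . import community as community_mod
from . import io as io_mod
from . import porewater as porewater_mod
from . import sediment as sediment_mod
from .errors import BenthofluxError, StageError
from .microprofile import MicroProfile, MicroprofileModel

CHAMBER_ANALYTES = ("O2", "DIC", "PO4", "NH4", "NO2", "NO3")


@dataclass(frozen=True)
class ScenarioPaths:
    """File locations of one scenario's input tables."""

    incubations: Path
    geometry: Path
    profiles: Path
    profiles_meta: Path
    porewater: Path
    layers: Path
    taxa: Path
    census: Path

    @classmethod
    def in_dir(cls, directory: str | Path) -> "ScenarioPaths":
        d = Path(directory)
        return cls(*(d / f"{name}.csv" for name in (
            "incubations", "geometry", "profiles", "profiles_meta",
            "porewater", "layers", "taxa", "census")))


def _geometry_lookup(geom_df: pd.DataFrame) -> dict[str, chamber_mod.ChamberGeometry]:
    out = {}
    for chamber_id, grp in geom_df.groupby("chamber_id"):
        out[chamber_id] = chamber_mod.ChamberGeometry(
            inner_diameter=float(grp["diameter_cm"].iloc[0]),
            height_readings=tuple(grp["height_cm"]),
        )
    return out


def _chamber_stage(inc: pd.DataFrame, geoms: dict, config: io_mod.RunConfig) -> pd.DataFrame:
    rows = []
    for (location, chamber_id), grp in inc.groupby(["location", "chamber_id"]):
        if chamber_id not in geoms:
            raise StageError("chamber", f"no geometry for chamber {chamber_id!r}")
        geom = geoms[chamber_id]
        light = grp["light"].iloc[0]
        series_by_analyte = {}
        for analyte, agrp in grp.sort_values("time_h").groupby("analyte"):
            series_by_analyte[analyte] = chamber_mod.IncubationSeries(
                analyte=analyte,
                times_h=tuple(agrp["time_h"]),
                concentrations=tuple(agrp["conc_umol_L"]),
                geometry=geom,
                light=light,
            )
        if "NOx" in series_by_analyte and "NO2" in series_by_analyte:
            series_by_analyte["NO3"] = chamber_mod.nitrate_series(
                series_by_analyte["NOx"], series_by_analyte["NO2"]
            )
        for analyte in CHAMBER_ANALYTES:
            if analyte not in series_by_analyte:
                continue
            res = chamber_mod.total_flux(series_by_analyte[analyte], alpha=config.alpha)
            rows.append({
                "location": location, "chamber_id": chamber_id, "light": light,
                "analyte": analyte, "flux": res.value, "qc": res.qc,
                "slope_p": res.slope_p,
            })
    return pd.DataFrame(rows)


def _microprofile_stage(
    prof: pd.DataFrame, meta: pd.DataFrame, config: io_mod.RunConfig
) -> pd.DataFrame:
    meta = meta.set_index("profile_id")
    rows = []
    for profile_id, grp in prof.groupby("profile_id"):
        if profile_id not in meta.index:
            raise StageError("microprofile", f"no metadata for profile {profile_id!r}")
        m = meta.loc[profile_id]
        grp = grp.sort_values("depth_mm")
        profile = MicroProfile(
            depths_mm=tuple(grp["depth_mm"]),
            o2_umol_l=tuple(grp["o2_umol_L"]),
            temperature=float(m["temperature_C"]),
            salinity=float(m["salinity_psu"]),
        )
        res = MicroprofileModel(
            profile,
            porosity_first_cm=float(m["porosity_first_cm"]),
            smoothing_window=config.smoothing_window,
            k=config.detection_k,
            span_mm=config.gradient_span_mm,
            anoxia_threshold=config.anoxia_threshold,
        ).fit()
        rows.append({
            "profile_id": profile_id, "dou": res.dou, "opd_mm": res.opd_mm, "qc": res.qc,
        })
    return pd.DataFrame(rows)


def _porewater_stage(
    pw: pd.DataFrame, porosity: float, temperature: float, salinity: float,
    config: io_mod.RunConfig,
) -> pd.DataFrame:
    rows = []
    # NOx and NO2 are grouped per core so nitrate can be derived by subtraction
    for core_id, cgrp in pw.groupby("core_id"):
        by_analyte = {a: g.sort_values("depth_cm") for a, g in cgrp.groupby("analyte")}
        targets = dict(by_analyte)
        if "NOx" in by_analyte and "NO2" in by_analyte:
            del targets["NOx"]
        for analyte, grp in targets.items():
            interval = tuple(config.porewater_intervals.get(analyte, porewater_mod.DEFAULT_INTERVAL))
            try:
                if analyte == "NO3":
                    continue  # only ever derived
                profile = porewater_mod.PoreWaterProfile(
                    analyte=analyte,
                    depths_cm=tuple(grp["depth_cm"]),
                    concentrations=tuple(grp["conc_umol_L"]),
                    porosity_mean=porosity,
                    temperature=temperature,
                    salinity=salinity,
                    flux_interval=interval,
                )
                res = porewater_mod.diffusive_flux(profile, alpha=config.alpha)
            except BenthofluxError as exc:
                raise StageError("porewater", f"{core_id}/{analyte}: {exc}") from exc
            rows.append({"core_id": core_id, "analyte": analyte,
                         "flux": res.value, "qc": res.qc, "slope_p": res.slope_p})
        if "NOx" in by_analyte and "NO2" in by_analyte:
            nox_grp, no2_grp = by_analyte["NOx"], by_analyte["NO2"]
            interval = tuple(config.porewater_intervals.get("NO3", porewater_mod.DEFAULT_INTERVAL))
            nox = porewater_mod.PoreWaterProfile(
                "NO3", tuple(nox_grp["depth_cm"]), tuple(nox_grp["conc_umol_L"]),
                porosity_mean=porosity, temperature=temperature, salinity=salinity,
                flux_interval=interval,
            )
            no2 = porewater_mod.PoreWaterProfile(
                "NO2", tuple(no2_grp["depth_cm"]), tuple(no2_grp["conc_umol_L"]),
                porosity_mean=porosity, temperature=temperature, salinity=salinity,
                flux_interval=interval,
            )
            derived = porewater_mod.nitrate_from_nox(nox, no2)
            res = porewater_mod.diffusive_flux(derived, alpha=config.alpha)
            rows.append({"core_id": core_id, "analyte": "NO3",
                         "flux": res.value, "qc": res.qc, "slope_p": res.slope_p})
    return pd.DataFrame(rows)


def _community_stage(
    taxa: pd.DataFrame, census: pd.DataFrame, config: io_mod.RunConfig
) -> pd.DataFrame:
    rows = []
    for location, grp in taxa.groupby("location"):
        cen = census[census["location"] == location]
        # location-specific photo-survey means are added to every grab replicate
        le_density = float(cen["laternula_density_ind_m2"].mean())
        le_biomass = float(cen["laternula_biomass_gC_m2"].mean())
        le_mi = int(cen["laternula_Mi"].iloc[0])
        le_ri = int(cen["laternula_Ri"].iloc[0])
        prok = community_mod.prokaryote_biomass(community_mod.ProkaryoteCensus(
            density=float(cen["prok_density_cells_cm3"].mean()),
            mean_cell_volume=float(cen["prok_cell_volume_um3"].mean()),
        ))
        meio_gC_m2 = float(cen["meio_biomass_ugC_10cm2"].mean()) * 1e-6 * 1e3  # -> g C m^-2
        bpcs, shannons, macro_excl = [], [], []
        for rep, rgrp in grp.groupby("replicate"):
            records = [
                community_mod.TaxonRecord(
                    r.taxon, r.density_ind_m2, r.biomass_gC_m2, int(r.Mi), int(r.Ri)
                )
                for r in rgrp.itertuples()
            ]
            le_record = community_mod.TaxonRecord(
                "Laternula elliptica", le_density, le_biomass, le_mi, le_ri
            )
            bpcs.append(community_mod.bpc(records + [le_record], config.bpc_variant))
            shannons.append(community_mod.shannon(records))
            macro_excl.append(rgrp["biomass_gC_m2"].sum())
        stocks = community_mod.SizeClassStocks(
            prokaryote=prok["areal"], meiofauna=meio_gC_m2,
            macrofauna_excl_le=float(np.mean(macro_excl)), laternula=le_biomass,
        )
        fractions = community_mod.stock_fractions(stocks)
        rows.append({
            "location": location,
            "bpc_mean": float(np.mean(bpcs)),
            "bpc_variant": config.bpc_variant,
            "shannon_mean": float(np.mean(shannons)),
            "macrofauna_excl_le_gC_m2": float(np.mean(macro_excl)),
            "laternula_gC_m2": le_biomass,
            "prokaryote_gC_m2": prok["areal"],
            "meiofauna_gC_m2": meio_gC_m2,
            "macrofauna_fraction_pct": fractions["macrofauna_fraction"],
            "laternula_share_pct": fractions["laternula_share_of_macrofauna"],
        })
    return pd.DataFrame(rows)


def run_pipeline(
    config: io_mod.RunConfig, inputs: ScenarioPaths, outdir: str | Path | None = None
) -> pd.DataFrame:
    """Run every stage and return (and optionally write) the tidy report.

    The report is long-format: location, metric, analyte (where applicable),
    value, unit, qc. When ``outdir`` is given, ``report.csv`` and ``run_log.txt``
    are written there.
    """
    def load(name: str, path: Path) -> pd.DataFrame:
        try:
            return io_mod.read_table(path, name)
        except BenthofluxError as exc:
            raise StageError(name, str(exc)) from exc

    layers = load("layers", inputs.layers)
    inc = load("incubations", inputs.incubations)
    geom = load("geometry", inputs.geometry)
    prof = load("profiles", inputs.profiles)
    prof_meta = load("profiles_meta", inputs.profiles_meta)
    pw = load("porewater", inputs.porewater)
    taxa = load("taxa", inputs.taxa)
    census = load("census", inputs.census)
    if inc.empty:
        raise StageError("chamber", f"{inputs.incubations}: no incubation rows")

    report_rows: list[dict] = []

    def add(location, metric, value, unit, analyte="", qc="ok"):
        report_rows.append({
            "location": location, "metric": metric, "analyte": analyte,
            "value": value, "unit": unit, "qc": qc,
        })

    try:
        sed_summary = sediment_mod.summarize_layers(layers)
    except BenthofluxError as exc:
        raise StageError("sediment", str(exc)) from exc
    for location, row in sed_summary.iterrows():
        add(location, "porosity", row["porosity"], "fraction")
        add(location, "cpe", row["cpe"], "ug g-1")
        add(location, "chl_to_phaeo", row["chl_to_phaeo"], "ratio")
        add(location, "tic", row["tic_ugC_mg"], "ug C mg-1")
        add(location, "toc_to_tc", row["toc_to_tc"], "fraction")

    fluxes = _chamber_stage(inc, _geometry_lookup(geom), config)
    for location, lgrp in fluxes.groupby("location"):
        o2 = lgrp[lgrp["analyte"] == "O2"]
        pool = None
        trans = o2[o2["light"] == "transparent"]["flux"]
        black = o2[o2["light"] == "black"]["flux"]
        if len(trans) >= 2 and len(black) >= 2:
            pool = chamber_mod.light_dark_pooling_check(trans, black, alpha=config.alpha)
            add(location, "light_dark_poolable", float(pool.poolable), "bool",
                analyte="O2", qc=pool.test)
        for analyte, agrp in lgrp.groupby("analyte"):
            ok = agrp[agrp["qc"] == "ok"]
            used = ok if not ok.empty else agrp
            qc = "ok" if not ok.empty else "all_flagged"
            add(location, "total_flux", float(used["flux"].mean()),
                "mmol m-2 d-1", analyte=analyte, qc=qc)
            n_flagged = int((agrp["qc"] != "ok").sum())
            if n_flagged:
                add(location, "omitted_chambers", float(n_flagged), "count",
                    analyte=analyte, qc="flagged")
        tou = -float(o2[o2["qc"] == "ok"]["flux"].mean()) if (o2["qc"] == "ok").any() else np.nan
        add(location, "tou", tou, "mmol O2 m-2 d-1 (uptake)")
        ctou = chamber_mod.carbon_equivalent(max(tou, 0.0)) if np.isfinite(tou) else np.nan
        add(location, "c_tou", ctou, "mmol C m-2 d-1")
        dic = lgrp[(lgrp["analyte"] == "DIC") & (lgrp["qc"] == "ok")]
        if not dic.empty and np.isfinite(tou) and tou > 0:
            add(location, "rq", float(abs(dic["flux"].mean()) / tou), "ratio")

    profile_report = _microprofile_stage(prof, prof_meta, config)
    locations = sorted(sed_summary.index)
    location = locations[0] if len(locations) == 1 else ""
    dou_mean = float(profile_report["dou"].mean())
    add(location, "dou", dou_mean, "mmol O2 m-2 d-1 (uptake)")
    add(location, "opd", float(profile_report["opd_mm"].dropna().mean()), "mm")

    porosity_mean = float(sed_summary["porosity"].mean())
    temperature = float(prof_meta["temperature_C"].mean())
    salinity = float(prof_meta["salinity_psu"].mean())
    pw_report = _porewater_stage(pw, porosity_mean, temperature, salinity, config)
    for analyte, agrp in pw_report.groupby("analyte"):
        add(location, "diffusive_flux", float(agrp["flux"].mean()),
            "mmol m-2 d-1", analyte=analyte,
            qc="ok" if (agrp["qc"] == "ok").any() else "all_flagged")
    # diffusive share of the total, where both exist
    totals = {r["analyte"]: r["value"] for r in report_rows
              if r["metric"] == "total_flux" and r["location"] in (location, locations[0])}
    for analyte, agrp in pw_report.groupby("analyte"):
        if analyte in totals and totals[analyte] != 0:
            add(location, "diffusive_share", float(abs(agrp["flux"].mean()) / abs(totals[analyte])),
                "fraction", analyte=analyte)

    community_report = _community_stage(taxa, census, config)
    for _, row in community_report.iterrows():
        loc = row["location"]
        add(loc, "bpc", row["bpc_mean"], f"score ({row['bpc_variant']})")
        add(loc, "shannon", row["shannon_mean"], "nats")
        add(loc, "macrofauna_fraction", row["macrofauna_fraction_pct"], "%")
        add(loc, "laternula_share", row["laternula_share_pct"], "%")

    tou_by_loc = {r["location"]: r["value"] for r in report_rows if r["metric"] == "tou"}
    ctou_by_loc = {r["location"]: r["value"] for r in report_rows if r["metric"] == "c_tou"}
    for loc, demand in ctou_by_loc.items():
        if not np.isfinite(demand):
            continue
        summary = _budget(
            demand, (config.supply_min_mmolC, config.supply_max_mmolC),
            dou=dou_mean, tou=tou_by_loc.get(loc),
        )
        add(loc, "budget_balance_min", summary.balance_min, "mmol C m-2 d-1")
        add(loc, "budget_balance_max", summary.balance_max, "mmol C m-2 d-1")
        add(loc, "budget_state", f"{summary.state_min}/{summary.state_max}", "state")
        if summary.dou_share_of_tou is not None:
            add(loc, "dou_share_of_tou", summary.dou_share_of_tou, "fraction")

    report = pd.DataFrame(report_rows)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        report.to_csv(outdir / "report.csv", index=False)
        qc_counts = report.groupby("qc").size().to_dict()
        log = [
            "benthoflux pipeline run",
            f"config: {config}",
            f"inputs: {inputs}",
            f"qc summary: {qc_counts}",
        ]
        (outdir / "run_log.txt").write_text("\n".join(log) + "\n")
    return report
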