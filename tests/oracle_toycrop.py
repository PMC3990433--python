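"""Independent straight-line reimplementation of the bundled toy crop model.

Hand-coded day loop with every equation written out explicitly and all
parameter values inlined as literals.  Deliberately shares no code with the
declarative engine; used only as the reference against which `simulate` is
checked.
"""

import math


def run_site_reference(tmin, tmax, rad, rain):
    """Return {variable: list of daily values} for one site (full model)."""
    n = len(tmin)
    tt = 0.0
    soil_water = 70.0
    lai = 0.02
    biomass = 1.0
    grain = 0.0
    cum_rain = 0.0
    out = {
        k: []
        for k in (
            "tmean", "soil_adj", "tsoil", "tt_rate", "tt", "vern_f",
            "leaf_num", "dev", "ctsw", "tcanopy", "transp", "soil_water",
            "drought_f", "rue_mod", "lai", "fint", "dbio", "biomass",
            "fill_mod", "tfac", "grain", "cum_rain", "harvest_index",
        )
    }
    for t in range(n):
        tmean = (tmin[t] + tmax[t]) / 2.0
        soil_adj = 0.004 * (rad[t] - 14.0)
        tsoil = tmean + soil_adj
        tt_rate = max(0.0, tsoil - 0.0)
        tt = tt + tt_rate
        vern_f = min(1.0, tt / 30.0)
        if tt >= (1.0 - vern_f) * 30.0:
            leaf_num = min(9.0, tt / 95.0)
        else:
            leaf_num = 0.0
        dev = tt / 1150.0
        ctsw = 1.0
        tcanopy = tmean + ctsw * 0.04 * (rad[t] - 14.0)
        transp = 2.1 * min(1.0, leaf_num / 9.0) * (0.55 + 0.45 * rad[t] / 14.0)
        soil_water = min(120.0, max(0.0, soil_water + rain[t] - transp))
        drought_f = min(1.0, soil_water / 55.0)
        rue_mod = 1.0 + 0.3 * (rad[t] / 14.0 - 1.0)
        if dev < 1.0:
            growth = 0.0009 * leaf_num * drought_f * max(0.0, tmean)
        else:
            growth = 0.0
        if dev >= 1.0:
            senescence = 0.055 * lai
        else:
            senescence = 0.0
        lai = max(0.0, lai + growth - senescence)
        fint = 1.0 - math.exp(-0.62 * lai)
        dbio = 1.15 * rad[t] * fint * rue_mod * drought_f
        biomass = biomass + dbio
        fill_mod = 1.0 + 1.2 * (tmean / (tmean + 6.0) - 0.62)
        tfac = max(0.2, 1.0 - abs(tcanopy - 18.0) / 25.0)
        if dev >= 1.0:
            fill = 9.0 * fill_mod * tfac
        else:
            fill = 0.0
        grain = min(0.6 * biomass, grain + fill)
        cum_rain = cum_rain + rain[t]
        harvest_index = grain / max(biomass, 1.0)
        for name, value in (
            ("tmean", tmean), ("soil_adj", soil_adj), ("tsoil", tsoil),
            ("tt_rate", tt_rate), ("tt", tt), ("vern_f", vern_f),
            ("leaf_num", leaf_num), ("dev", dev), ("ctsw", ctsw),
            ("tcanopy", tcanopy), ("transp", transp),
            ("soil_water", soil_water), ("drought_f", drought_f),
            ("rue_mod", rue_mod), ("lai", lai), ("fint", fint),
            ("dbio", dbio), ("biomass", biomass), ("fill_mod", fill_mod),
            ("tfac", tfac), ("grain", grain), ("cum_rain", cum_rain),
            ("harvest_index", harvest_index),
        ):
            out[name].append(value)
    return out
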