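# worldseasons

A two-tier global seasonal classification for climate and ecological analysis.
Many phenomena that matter for comparative research — monsoons, harvests,
snow melt, fire seasons — are seasonal, yet analyses routinely aggregate them
by calendar year, diluting signal with months that are irrelevant to the
question. `worldseasons` assigns every land grid cell an empirically derived
season calendar, so the temporal frame of an analysis can be matched to local
climate the way biome maps match its spatial frame.

## The method

**Tier 1 — climate zone.** Each cell is assigned one of four zones by fixed
threshold rules, evaluated in order:

1. **Desert** if the annual Aridity Index AI = ΣP / ΣPET < 0.2 (P monthly
   precipitation, PET potential evapotranspiration). Aridity is tested first
   so cold arid regions (Gobi, Tibetan plateau, dry tundra) classify as
   deserts rather than arctic.
2. **Arctic / high montane** if the monthly-mean minimum temperature never
   exceeds 10 °C — a frost is possible in any month.
3. **Tropical** if ΔP = max P − min P > 81.972 mm **and**
   ΔT = max T − min T < 7.52 °C **and** the coldest month's temperature
   midpoint T = (Tmin + Tmax)/2 is at least 18 °C.
4. **Temperate** otherwise.

**Tier 2 — seasons.** The 12 months of a cell are clustered by k-means in a
zone-specific feature space (columns z-scored, then scaled by √w so a weight
w multiplies a variable's squared-distance contribution by w):

| zone | features (weights) | k | season names |
|---|---|---|---|
| temperate | T (3.521), ΔP lag (3.237), ΔT lag (2.031), ΔNDVI lag (0.312) | 4 | winter, spring, summer, autumn |
| tropical | T (3.958), ΔP lag (3.72), ΔNDVI lag (1.713) | 2 | wet, dry |
| arctic | T, solar radiation (unweighted) | 2 | winter, summer |
| desert | T, monthly aridity (unweighted) | 2 | cooler, hotter |

"Lag" variables are circular month-over-month differences (January minus
December), capturing the size and direction of change that separates, e.g.,
spring from autumn. Outside the tropics seasons must be *temporally
contiguous* — one circular run of months each — so raw k-means labels are
projected onto the nearest contiguous partition; tropical cells may keep
multiple wet seasons (the ITCZ crosses the inner tropics twice a year).

The two thresholds and seven weights above are the nine free parameters of
the classifier. They ship as defaults, and the `tuning` module can re-fit
them by budgeted random search against reference season calendars, scored by
a per-city error (mismatching months, capped at 6 when the predicted and
reference calendars disagree about the temperate/tropical zone itself).

## Worked example

```python
import numpy as np
from worldseasons import ArchetypeSpec, make_pixel, classify_pixel

pixel, truth = make_pixel(ArchetypeSpec("temperate", hemisphere="N"))
cal = classify_pixel(pixel)
print(cal.zone.name)
print(cal.names())
```

prints

```
TEMPERATE
['winter', 'winter', 'spring', 'spring', 'spring', 'summer', 'summer',
 'summer', 'autumn', 'autumn', 'autumn', 'winter']
```

— a northern-hemisphere four-season calendar whose winter (Dec–Feb) contains
the coldest month of the generated sinusoidal climate. A bimodal tropical
pixel instead yields two wet runs:

```python
pixel, _ = make_pixel(ArchetypeSpec("tropical_bimodal"))
print(classify_pixel(pixel).names())
```

```
['wet', 'dry', 'dry', 'dry', 'wet', 'wet', 'wet', 'dry', 'dry', 'dry',
 'wet', 'wet']
```

## Command line

```bash
worldseasons synth --archetype temperate --width 20 --height 20 --out demo/
worldseasons zones --climate-dir demo/ --out demo/zones.tif
worldseasons classify --climate-dir demo/ --smooth-window 3 --out demo/out/
worldseasons optimize --reference ref.csv --climate-dir demo/ --budget 2000 \
    --seed 1 --out params.yaml
```

`classify` writes the standard output formats: a 12-band uint8 GeoTIFF of
season codes, a single-band zone GeoTIFF, and a long-format text table with
columns `x, y, month, season`. `--equal-earth` reprojects outputs to the
equal-area Equal Earth projection (EPSG:8857).

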