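# Harmonization table for GlobeLand30 (NGCC), built against the official
# 10-class v2020 legend (codes 10..100).
dataset_id: globeland30
legend: "GlobeLand30 v2020 official 10-class legend"
classes:
  - {native_code: 10, native_label: "Cultivated land", harmonized_code: CULTIVATED,
     note: "Includes cultivated grassland (pasture); excludes tree crops."}
  - {native_code: 20, native_label: "Forest", harmonized_code: FOREST}
  - {native_code: 30, native_label: "Grassland", harmonized_code: GRASS_SHRUB}
  - {native_code: 40, native_label: "Shrubland", harmonized_code: GRASS_SHRUB}
  - {native_code: 50, native_label: "Wetland", harmonized_code: NONFOREST_WETLAND,
     note: "GlobeLand30 cannot split forested wetland out; the entire wetland class
            is treated as non-forested wetland and never as forestland."}
  - {native_code: 60, native_label: "Water bodies", harmonized_code: OTHER}
  - {native_code: 70, native_label: "Tundra", harmonized_code: OTHER,
     note: "Tundra is kept out of grassland & shrubland; products disagree on it."}
  - {native_code: 80, native_label: "Artificial surfaces", harmonized_code: OTHER}
  - {native_code: 90, native_label: "Bareland", harmonized_code: OTHER}
  - {native_code: 100, native_label: "Permanent snow and ice", harmonized_code: OTHER}
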