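# Harmonization table for GLC_FCS30D, built against the fine classification
# system legend (level-1/level-2 integer codes).
dataset_id: glc_fcs30d
legend: "GLC_FCS30D fine classification system legend (basic + wetland subclasses)"
classes:
  - {native_code: 10, native_label: "Rainfed cropland", harmonized_code: CULTIVATED}
  - {native_code: 11, native_label: "Herbaceous cover cropland", harmonized_code: CULTIVATED}
  - {native_code: 12, native_label: "Tree or shrub cover cropland (orchard)",
     harmonized_code: CULTIVATED,
     note: "Tree crops are part of the cropland class in this product."}
  - {native_code: 20, native_label: "Irrigated cropland", harmonized_code: CULTIVATED}
  - {native_code: 51, native_label: "Open evergreen broadleaved forest", harmonized_code: FOREST}
  - {native_code: 52, native_label: "Closed evergreen broadleaved forest", harmonized_code: FOREST}
  - {native_code: 61, native_label: "Open deciduous broadleaved forest", harmonized_code: FOREST}
  - {native_code: 62, native_label: "Closed deciduous broadleaved forest", harmonized_code: FOREST}
  - {native_code: 71, native_label: "Open evergreen needleleaved forest", harmonized_code: FOREST}
  - {native_code: 72, native_label: "Closed evergreen needleleaved forest", harmonized_code: FOREST}
  - {native_code: 81, native_label: "Open deciduous needleleaved forest", harmonized_code: FOREST}
  - {native_code: 82, native_label: "Closed deciduous needleleaved forest", harmonized_code: FOREST}
  - {native_code: 91, native_label: "Open mixed-leaf forest", harmonized_code: FOREST}
  - {native_code: 92, native_label: "Closed mixed-leaf forest", harmonized_code: FOREST}
  - {native_code: 120, native_label: "Shrubland", harmonized_code: GRASS_SHRUB}
  - {native_code: 121, native_label: "Evergreen shrubland", harmonized_code: GRASS_SHRUB}
  - {native_code: 122, native_label: "Deciduous shrubland", harmonized_code: GRASS_SHRUB}
  - {native_code: 130, native_label: "Grassland", harmonized_code: GRASS_SHRUB}
  - {native_code: 140, native_label: "Lichens and mosses (tundra)", harmonized_code: OTHER,
     note: "Tundra is kept separate from grassland & shrubland."}
  - {native_code: 150, native_label: "Sparse vegetation", harmonized_code: OTHER}
  - {native_code: 152, native_label: "Sparse shrubland", harmonized_code: OTHER}
  - {native_code: 153, native_label: "Sparse herbaceous cover", harmonized_code: OTHER}
  - {native_code: 181, native_label: "Swamp", harmonized_code: FOREST,
     note: "Swamp is covered with woody vegetation and counts as forestland;
            conservative for non-forested wetland."}
  - {native_code: 182, native_label: "Marsh", harmonized_code: NONFOREST_WETLAND}
  - {native_code: 183, native_label: "Flooded flat", harmonized_code: NONFOREST_WETLAND}
  - {native_code: 184, native_label: "Saline", harmonized_code: NONFOREST_WETLAND}
  - {native_code: 185, native_label: "Mangrove", harmonized_code: FOREST,
     note: "Mangrove is woody vegetation and counts as forestland."}
  - {native_code: 186, native_label: "Salt marsh", harmonized_code: NONFOREST_WETLAND}
  - {native_code: 187, native_label: "Tidal flat", harmonized_code: NONFOREST_WETLAND}
  - {native_code: 190, native_label: "Impervious surface", harmonized_code: OTHER}
  - {native_code: 200, native_label: "Bare areas", harmonized_code: OTHER}
  - {native_code: 201, native_label: "Consolidated bare areas", harmonized_code: OTHER}
  - {native_code: 202, native_label: "Unconsolidated bare areas", harmonized_code: OTHER}
  - {native_code: 210, native_label: "Water body", harmonized_code: OTHER}
  - {native_code: 220, native_label: "Permanent ice and snow", harmonized_code: OTHER}
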