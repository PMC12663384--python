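# Identity table for synthetic landscapes, which are generated directly in
# harmonized codes.
dataset_id: synthetic
legend: "identity over harmonized codes"
classes:
  - {native_code: 1, native_label: "Cultivated", harmonized_code: CULTIVATED}
  - {native_code: 2, native_label: "Grassland & shrubland", harmonized_code: GRASS_SHRUB}
  - {native_code: 3, native_label: "Non-forested wetland", harmonized_code: NONFOREST_WETLAND}
  - {native_code: 4, native_label: "Forestland", harmonized_code: FOREST}
  - {native_code: 5, native_label: "Other", harmonized_code: OTHER}
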