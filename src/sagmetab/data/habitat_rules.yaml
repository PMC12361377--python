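# Fixture habitat keyword flags and flag-combination classes for free-text
# genome metadata. Rows in `combinations` are ordered most-specific first;
# the first row whose flags are all raised assigns the habitat class.
flags:
  freshwater: [lake, lentic, freshwater, river, stream, pond, limnic]
  marine: [marine, seawater, ocean, oceanic, estuary, brine]
  sediment: [sediment, sediments, mud, core]
  soil: [soil, permafrost, rhizosphere]
  groundwater: [groundwater, aquifer, borehole]
  glacial_ice: [glacier, glacial, subglacial, ice, icecap, cryoconite]
  wastewater: [wastewater, sludge, sewage, bioreactor]
  host_associated: [gut, rumen, faeces, feces, host-associated, intestinal]
combinations:
  - {flags: [glacial_ice, sediment], habitat: subglacial sediment}
  - {flags: [glacial_ice, freshwater], habitat: subglacial freshwater}
  - {flags: [freshwater, sediment], habitat: freshwater sediment}
  - {flags: [marine, sediment], habitat: marine sediment}
  - {flags: [glacial_ice], habitat: glacial ice}
  - {flags: [freshwater], habitat: freshwater}
  - {flags: [marine], habitat: marine}
  - {flags: [groundwater], habitat: groundwater}
  - {flags: [wastewater], habitat: wastewater}
  - {flags: [host_associated], habitat: host-associated}
  - {flags: [soil], habitat: soil}
  - {flags: [sediment], habitat: sediment}
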