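# 2018 Environmental Performance Index hierarchy: policy objectives,
# issue categories and indicators with their published relative weights.
name: EPI 2018
objectives:
  - name: Environmental Health
    code: HLT
    weight: 40%
    categories:
      - name: Air Quality
        code: AIR
        weight: 65%
        indicators:
          - {name: Household Solid Fuels, code: HAD, weight: 40%}
          - {name: PM2.5 Exposure, code: PME, weight: 30%}
          - {name: PM2.5 Exceedance, code: PMW, weight: 30%}
      - name: Water & Sanitation
        code: H2O
        weight: 30%
        indicators:
          - {name: Drinking Water, code: UWD, weight: 50%}
          - {name: Sanitation, code: USD, weight: 50%}
      - name: Heavy Metals
        code: HMT
        weight: 5%
        indicators:
          - {name: Lead Exposure, code: PBD, weight: 100%}
  - name: Ecosystem Vitality
    code: ECO
    weight: 60%
    categories:
      - name: Biodiversity & Habitat
        code: BDH
        weight: 25%
        indicators:
          - {name: Marine Protected Areas, code: MPA, weight: 20%}
          - {name: Biome Protection (National), code: TBN, weight: 20%}
          - {name: Biome Protection (Global), code: TBG, weight: 20%}
          - {name: Species Protection Index, code: SPI, weight: 20%}
          - {name: Representativeness Index, code: PAR, weight: 10%}
          - {name: Species Habitat Index, code: SHI, weight: 10%}
      - name: Forests
        code: FOR
        weight: 10%
        indicators:
          - {name: Tree Cover Loss, code: TCL, weight: 100%}
      - name: Fisheries
        code: FSH
        weight: 10%
        indicators:
          - {name: Fish Stock Status, code: FSS, weight: 50%}
          - {name: Regional Marine Trophic Index, code: MTR, weight: 50%}
      - name: Climate & Energy
        code: CCE
        weight: 30%
        indicators:
          - {name: CO2 Emissions - Total, code: DCT, weight: 50%}
          - {name: CO2 Emissions - Power, code: DPT, weight: 20%}
          - {name: Methane Emissions, code: DMT, weight: 20%}
          - {name: N2O Emissions, code: DNT, weight: 5%}
          - {name: Black Carbon Emissions, code: DBT, weight: 5%}
      - name: Air Pollution
        code: APE
        weight: 10%
        indicators:
          - {name: SO2 Emissions, code: DST, weight: 50%}
          - {name: NOx Emissions, code: DXT, weight: 50%}
      - name: Water Resources
        code: WRS
        weight: 10%
        indicators:
          - {name: Wastewater Treatment, code: WWT, weight: 100%}
      - name: Agriculture
        code: AGR
        weight: 5%
        indicators:
          - {name: Sustainable Nitrogen Management, code: SNM, weight: 100%}
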