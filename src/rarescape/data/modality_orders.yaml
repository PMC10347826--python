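# Declared modality orders for the ordered categorical morpho-trophic traits.
# Each order is ascending: the first modality encodes to 0, the last to k-1.
# Motility, Symbiosis and PlastOrigin orders follow the published gradients
# (growing motility investment / parasitism ranked highest / growing
# phototrophy); the remaining orders are editable reconstructions.
CellCover: [None, Mucilage, Organic, Siliceous, Calcareous]
CellShape: [Spherical, Ovoid, Elongated, Complex]
Spicule: [Absent, Present]
CellSymmetry: [Asymmetric, Radial, Bilateral]
CellPolarity: [Absent, Present]
Colony: [Never, Facultative, Always]
Motility: [Attached, Floating, Gliding, Swimming]
Ingestion: [None, Osmotrophy, Saprotrophy, Phagotrophy]
Symbiosis: [None, Commensal, Mutualistic, Parasitic]
RestingStage: [Absent, Present]
PlastOrigin: [None, Kleptoplastidic, Endosymbiotic, Constitutive]
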