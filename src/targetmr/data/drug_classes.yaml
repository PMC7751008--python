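# Antihypertensive drug classes (British National Formulary) with
# illustrative protein-target gene lists. The gene lists are placeholders:
# real analyses should supply their own curated class -> target mapping
# (e.g. from a licensed DrugBank export), which this file's format mirrors.
- class: adrenergic neurone blocking drugs
  genes: [SLC6A2]
- class: alpha-adrenoceptor blockers
  genes: [ADRA1A, ADRA1B, ADRA1D]
- class: angiotensin-converting enzyme inhibitors
  genes: [ACE]
- class: angiotensin-II receptor blockers
  genes: [AGTR1]
- class: beta-adrenoceptor blockers
  genes: [ADRB1, ADRB2]
- class: calcium channel blockers
  genes: [CACNA1C, CACNA1D, CACNA2D1, CACNB2]
- class: centrally acting antihypertensive drugs
  genes: [ADRA2A, HTR1A]
- class: loop diuretics
  genes: [SLC12A1]
- class: potassium-sparing diuretics and aldosterone antagonists
  genes: [NR3C2, SCNN1A, SCNN1G]
- class: renin inhibitors
  genes: [REN]
- class: thiazides and related diuretics
  genes: [SLC12A3]
- class: vasodilator antihypertensives
  genes: [KCNJ8, PDE5A]
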