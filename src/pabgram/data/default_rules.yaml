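# Default susceptibility imputation rule table.
#
# Edit or replace this file to adapt the labeler to local microbiology
# practice; the labeler treats it as data, not code.
#
# Targets on the left-hand side of a rule are either an organism name or
# "group:<name>" referring to an entry under `groups`. Right-hand sides of
# intrinsic_resistance rules are single antibiotics; right-hand sides of
# intrinsic_susceptibility rules are antibiotic class names defined under
# `antibiotic_classes`.

groups:
  gram_negative_rod:
    - Escherichia coli
    - Klebsiella pneumoniae
    - Proteus mirabilis
    - Pseudomonas aeruginosa
  enterococcus:
    - Enterococcus faecalis
    - Enterococcus faecium
  mrsa:
    - Staphylococcus aureus (MRSA)

antibiotic_classes:
  cephalosporin:
    - generation: 1
      members: [cefazolin]
    - generation: 3
      members: [ceftriaxone]
    - generation: 4
      members: [cefepime]

intrinsic_resistance:
  - [Pseudomonas aeruginosa, ceftriaxone]
  - [Pseudomonas aeruginosa, cefazolin]
  - ["group:gram_negative_rod", vancomycin]
  - ["group:enterococcus", cefazolin]
  - ["group:enterococcus", ceftriaxone]
  - ["group:enterococcus", cefepime]
  # methicillin resistance implies resistance across the beta-lactams
  - ["group:mrsa", ampicillin]
  - ["group:mrsa", cefazolin]
  - ["group:mrsa", ceftriaxone]
  - ["group:mrsa", cefepime]
  - ["group:mrsa", "piperacillin/tazobactam"]
  - ["group:mrsa", meropenem]

intrinsic_susceptibility:
  - [Streptococcus agalactiae, cephalosporin]
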