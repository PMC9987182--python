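synthetic:
  seed: 7
  n_users: 2000
  window_start: '2019-10-27'
  window_end: '2020-06-08'
  activity:
    name: lognormal
    location: 0.0
    scale: 1.2
  retweet_fraction: 0.3
  roles:
  - label: self_promoter
    proportion: 0.25
    keywords:
    - blogger
    - writer
    - author
    - vegan
    - foodie
    inclusion_prob: 0.4
  - label: family
    proportion: 0.25
    keywords:
    - mom
    - mother
    - wife
    - dad
    - husband
    inclusion_prob: 0.35
  - label: clinician
    proportion: 0.05
    keywords:
    - doctor
    - dietitian
    - physician
    - phd
    - md
    inclusion_prob: 0.5
  - label: general
    proportion: 0.45
    keywords: []
    inclusion_prob: 0.0
  anchor:
    label: glutenfree
    tags:
      glutenfree: 0.8
      glutenfreediet: 0.2
  cotag_probs:
    vegan: 0.18
    dairyfree: 0.06
    keto: 0.03
    recipe: 0.05
    celiac: 0.03
    gluten: 0.02
    gf: 0.02
  url_emission_prob: 0.25
  domain_probs:
    instagram.com: 0.35
    youtu.be: 0.15
    celiac.com: 0.12
    bit.ly: 0.08
    blog.example.com: 0.14
    nonprofit.org: 0.1
    health.example.gov: 0.01
    pinterest.com: 0.05
spaces:
- label: glutenfree
  synonym_tags:
  - glutenfree
  - glutenfreediet
  exclusion_stems:
  - gluten
  excluded_abbreviations:
  - gf
- label: celiac
  synonym_tags:
  - celiac
  - celiacdisease
  - coeliac
  - coeliacdisease
  exclusion_stems:
  - celiac
  - coeliac
top_n: 15
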