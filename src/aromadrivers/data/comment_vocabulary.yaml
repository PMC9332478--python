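# Controlled vocabulary for open-comment terms: 18 liked + 18 disliked.
# SYNTHETIC in part: only the terms marked [reported] appear verbatim in the
# published consumer comments; the remaining entries are representative
# placeholders invented to complete the 18+18 layout of the comment heatmap.
liked:
  - rich vinegar aroma            # [reported]
  - medium vinegar aroma          # [reported]
  - fruity vinegar aroma          # [reported]
  - sweet aroma                   # [reported]
  - soft vinegar aroma
  - mellow aroma
  - fresh aroma
  - grain aroma
  - caramel aroma
  - smoked aroma
  - rice aroma
  - mild sour aroma
  - clean aroma
  - balanced aroma
  - floral aroma
  - honey aroma
  - roasted aroma
  - familiar aroma
disliked:
  - too pungent vinegar aroma     # [reported]
  - not rich vinegar aroma        # [reported]
  - alcohol aroma                 # [reported]
  - smelly aroma                  # [reported]
  - chinese medicine aroma        # [reported]
  - musty aroma
  - burnt aroma
  - harsh sour aroma
  - watery aroma
  - stale aroma
  - chemical aroma
  - earthy aroma
  - fishy aroma
  - moldy aroma
  - too sweet aroma
  - metallic aroma
  - flat aroma
  - unfamiliar aroma
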