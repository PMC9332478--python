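# Default aroma-category map: category -> descriptor terms as they appear in
# the compound catalog's "descriptors" field (lowercase, comma-split).
# The nine classic aroma elements (fruity, floral, herbaceous, nutty, caramel,
# earthy, chemical, fatty, roasted) are extended with sour, green, sweet and
# fragrant, which the product aroma summaries use as well.
fruity:
  - fruity
  - grape
  - pineapple
  - apple
  - banana
  - pear
  - citrus
  - sweet fruit
  - cherries
  - lemon green
floral:
  - floral
  - floral scent
  - honey
  - honey aroma
herbaceous:
  - green
  - grassy
  - vegetable
  - herbal
  - baking and grassy notes
nutty:
  - nuts
  - nutty
  - almonds
  - almond
  - roasted almonds
  - peanuts
  - fried peanuts
  - cocoa
  - bitter cocoa
  - chocolate
caramel:
  - caramel
earthy:
  - earthy
  - earthy notes
  - soily
  - mildew
  - baked potatoes
chemical:
  - solvent
  - ether
  - etheric
  - chemicals
  - coal tar smell
  - coal tar
  - aromatic odor
  - camphor
  - strong phenolic smell
  - strong medicinal
fatty:
  - fat
  - waxy
  - cream
  - creamy
  - butter
  - milk
  - cheese
roasted:
  - roasted
  - roasted incense
  - baked incense
  - smoky
  - smoked
  - rum
sour:
  - strong sour taste
  - spicy and sour
  - pungent and spicy roquefort
green:
  - green
  - grassy
  - lemon green
sweet:
  - sweet
  - slightly sweet aroma
  - honey
fragrant:
  - fragrant
  - fresh bread aroma
  - weak pleasing aroma
  - pleasant
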