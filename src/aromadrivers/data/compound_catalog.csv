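compound_id,name,retention_index,identification,class,quant_ion,descriptors,odor_threshold,odor_threshold_implied
1,ethyl acetate,878,"MS, RI",Ester,43,"sweet, etheric, fruity, grape, rum","5,000","5,000"
2,ethyl propionate,958,"MS, RI",Ester,75,"sweet, fruity, grape, ether, rum, pineapple",10,10
3,n-propyl acetate,974,"MS, RI",Ester,43,"pleasant, solvent, sweet fruit","150,000","150,000"
4,isobutyl acetate,1012,"MS, RI",Ester,43,"sweet, apple, banana, fruity",66,66
5,isoamyl acetate,1110,"MS, RI",Ester,43,"sweet, pear, banana, fruity",—,—
6,"1,2-propanediol,2-acetate",1621,"MS, RI",Ester,43,—,—,—
7,trimethylene acetate,1665,"MS, RI",Ester,43,—,11,11
8,ethyl benzoate,1681,"MS, RI",Ester,105,"sweet, fruity, fragrant",60,60
9,diethyl succinate,1680,"MS, RI",Ester,101,weak pleasing aroma,"2,000","2,000"
10,ethyl phenylacetate,1770,"MS, RI",Ester,91,"sweet, fruity, cocoa, floral scent, honey aroma",650,650
11,β-phenethyl acetate,1788,"MS, RI",Ester,104,"sweet, green, floral, fruity, citrus, honey","3,900","3,900"
12,3-methylbutyraldehyde,924,"MS, RI",Aldehyde,44,"apple, chocolate, cocoa",—,—
13,nonanal,1386,"MS, RI",Aldehyde,57,"fat, floral, waxy, citrus",1,1
14,benzaldehyde,1520,"MS, RI",Aldehyde,77,"almonds, cherries, nuts, woody","3,500","3,500"
15,phenylethanal,1638,"MS, RI",Aldehyde,91,"green, earthy, chocolate",4,4
16,1H-pyrrole-2-carbaldehyde,2009,"MS, RI",Aldehyde,95,—,—,—
17,5-methyl-2-phenyl-2-hexenal,2060,"MS, RI",Aldehyde,117,"bitter cocoa, nuts, honey, baking and grassy notes",—,—
18,1-methylpyrrole-2-carboxaldehyde,2009,"MS, RI",Aldehyde,95,—,—,—
19,acetic acid,1449,"MS, RI",Acid,60,strong sour taste,"2,200","2,200"
20,propionic acid,1522,"MS, RI",Acid,74,spicy and sour,"20,000","20,000"
21,butyric acid,1620,"MS, RI",Acid,60,"cheese, milk, cream, fruity",240,240
22,isovaleric acid,1680,"MS, RI",Acid,60,"cheese, products, fruity",700,700
23,2-methylbutyric acid,1685,"MS, RI",Acid,74,pungent and spicy Roquefort,20,70
24,caproic acid,1880,"MS, RI",Acid,60,"green, woody, grassy, vegetable, meaty, fruity","3,000","3,000"
25,octanoic acid,2100,"MS, RI",Acid,60,sweet,"3,000","3,000"
26,3-methyl-1-butanol,1185,"MS, RI",Alcohol,55,"apple, banana, whiskey","30,000","30,000"
27,"2,3-butanediol",1584,"MS, RI",Alcohol,45,"sweet, butter, butter","100,000","100,000"
28,phenethyl alcohol,1890,"MS, RI",Alcohol,91,"sweet, green, floral, fresh bread aroma",750,750
29,3-hydroxy-2-butanone,1270,"MS, RI",Ketone,45,—,140,140
30,acetophenone,1656,"MS, RI",Ketone,105,"cream, fat",65,65
31,2-pyrrolidinone,2037,"MS, RI",Ketone,42,"strong medicinal, almond",—,—
32,guaiacol,1862,"MS, RI",Phenol,109,"smoked, spicy, fragrant, meaty, woody",21,21
33,2-ethyl-3-hydroxy-4H-pyran-4-one,2052,"MS, RI",Phenol,140,"fruity, caramel",—,—
34,4-ethyl-2-methoxyphenol,2031,"MS, RI",Phenol,137,"sweet, spicy, herbal",—,—
35,4-ethylphenol,2199,"MS, RI",Phenol,107,"strong phenolic smell, slightly sweet aroma",—,—
36,furfural,1462,"MS, RI",Furan,96,"strong phenolic smell, slightly sweet aroma","3,000","3,000"
37,acetylfuran,1508,"MS, RI",Furan,95,"baked incense, smoky","10,000","10,000"
38,furfuryl acetate,1525,"MS, RI",Furan,81,"ester, floral",—,—
39,"1-pentanone, 1-(2-furanyl)-",1563,"MS, RI",Furan,95,—,6,6
40,3-furanmethanol,1679,"MS, RI",Furan,98,caramel,—,—
41,1-(5-methyl-2-furyl)ethan-1-one,1606,"MS, RI",Furan,109,"biscuits, roasted almonds",—,—
42,4-(2-furyl)-3-buten-2-one,1879,"MS, RI",Furan,121,"sweet, powdery, nutty, creamy, woody cinnamon",—,—
43,5-acetyldihydrofuran-2(3H)-one,2160,"MS, RI",Furan,85,"sweet, lemon green",65,65
44,2-methylpyrazine,1266,"MS, RI",Pyrazine,94,"nuts, peanuts, roasted incense, soily, mildew",60,60
45,"2,3-dimethyl pyrazine",1356,"MS, RI",Pyrazine,67,"mildew, roasted, creamy, nuts, cocoa, coffee","2,500","2,500"
46,"2,3,5-trimethylpyrazine",1415,"MS, RI",Pyrazine,42,"baked potatoes, fried peanuts, nuts, earthy notes, fermented",400,"1,800"
47,"1,3-dioxolane,2,4,5-trimethyl-",967,"MS, RI",Others,44,—,—,—
48,"1,3-dioxane, 2-methyl-",1044,"MS, RI",Others,87,—,—,—
49,naphthalene,1744,"MS, RI",Others,128,"aromatic odor, coal tar smell","1,500","1,500"
50,2-methylnaphthalene,1839,"MS, RI",Others,142,"aromatic odor, coal tar, camphor, chemicals",—,—
51,2-phenylthiophene,2124,"MS, RI",Others,160,—,—,—
52,4-acetoxy-3-methoxystyrene,2235,"MS, RI",Others,150,—,—,—
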