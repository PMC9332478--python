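code,product_name,net_content_ml,origin,product_type
B1,Ten-year aged Qian-he cellar vinegar,500,"Meishan, Sichuan Province",Mature vinegar
B2,Ning-hua-mansion old vinegar,500,"Taiyuan, Shanxi Province",Mature vinegar
B3,East-lake health vinegar,500,"Taiyuan, Shanxi Province",Health vinegar
B4,Qian-he glutinous rice vinegar,500,"Meishan, Sichuan Province",Aromatic vinegar
B5,Heng-shun Jinyou balsamic vinegar,360,"Zhenjiang, Jiangsu Province",Aromatic vinegar
B6,Potato vinegar,1750,"Ulanqab, Inner Mongolia",Potato vinegar
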