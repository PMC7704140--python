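"""Built-in corpus: 17 published Chinese-herbal-bath-therapy (CHBT) formulas.

The corpus comes from a meta-analysis of 17 randomized controlled trials of
whole-body herbal baths for uremic pruritus. Each entry is the study label and
its prescription's herb list in the order the trial reported it. The lexicon
carries, for each of the 43 distinct herbs, its pinyin name, an English common
name, the Latin binomial, and the number of the 17 formulas that use it.

Herb names here are already in normalized (lowercase pinyin) form; the
published source capitalizes the first herb of each list, which is a
typographic artifact, not a different item.
"""

# (study_label, ordered herb list) — one tuple per trial.
PAPER_FORMULAS: tuple[tuple[str, tuple[str, ...]], ...] = (
    ("Du, 2009",
     ("tufulin", "chuanxiong", "baizhi", "baixianpi", "difuzi", "kushen",
      "jingjie", "xixin", "danggui", "chantui")),
    ("Du et al., 2004",
     ("tufulin", "chuanxiong", "baixianpi", "difuzi", "heshouwu", "kushen",
      "jingjie", "xixin", "danggui")),
    ("Gao and Ye, 2012",
     ("tufulin", "dahuang", "baixianpi", "difuzi", "heshouwu", "fangfeng",
      "taoren", "mahuang", "danshen", "jixueteng")),
    ("Guo et al., 2009",
     ("dahuang", "chuanxiong", "danshen", "baixianpi", "difuzi", "honghua",
      "kushen", "xixin", "mahuang", "danggui")),
    ("Jia et al., 2012",
     ("dahuang", "chuanxiong", "baizhi", "baixianpi", "difuzi", "zaojiaoci",
      "kushen", "xixin", "danggui", "chantui", "jixueteng")),
    ("Jia, Li and Fei, 2012",
     ("dahuang", "chuanxiong", "baizhi", "baixianpi", "difuzi", "zaojiaoci",
      "kushen", "xixin", "danggui", "chantui", "jixueteng")),
    ("Lan, 2017",
     ("dahuang", "chuanxiong", "danshen", "baixianpi", "difuzi", "honghua",
      "kushen", "xixin", "mahuang", "danggui")),
    ("Lin, 2014",
     ("dahuang", "chuanxiong", "baizhi", "baixianpi", "difuzi", "zaojiaoci",
      "kushen", "xixin", "danggui", "chantui", "jixueteng")),
    ("Shen, 2014",
     ("tufulin", "danshen", "baixianpi", "quanxie", "difuzi", "heshouwu",
      "kushen", "xixin", "shechuangzi", "mahuang", "danggui", "wugong",
      "chantui", "biejia")),
    ("Wang et al., 2013",
     ("dahuang", "chuanxiong", "baixianpi", "difuzi", "chishao", "kushen",
      "xixin", "shechuangzi", "juhua", "danggui", "chantui")),
    ("Wen, 2007",
     ("tufulin", "chuanxiong", "baijili", "difuzi", "wushaoshe", "jingjie",
      "xixin", "danggui", "jixueteng")),
    ("Yao, 2015",
     ("tufulin", "baixianpi", "difuzi", "kushen", "jingjie", "chantui")),
    ("Yu et al., 2017",
     ("tufulin", "chuanxiong", "baixianpi", "difuzi", "kushen", "jingjie",
      "zisuye", "danggui", "jixuecao", "chantui")),
    ("Zhang et al., 2014",
     ("tufulin", "difuzi", "baixianpi", "kushen", "chantui", "jingjie")),
    ("Zhang et al., 2012",
     ("baizhi", "baijili", "fangfeng", "songjie", "qianghuo", "guizhi",
      "jingjie", "xixin", "shechuangzi", "mahuang", "cangzhu", "tanxiang",
      "chantui")),
    ("Zhao, 2011",
     ("wujiapi", "baizhi", "baijili", "shenjincao", "fangfeng", "peilan",
      "songjie", "qianghuo", "weilingxian", "guizhi", "taozhi", "haitongpi",
      "jingjie", "xixin", "shechuangzi", "mahuang", "zisuye", "huaizhi",
      "cangzhu", "tanxiang", "chantui", "huoxiang")),
    ("Zheng, 2016",
     ("chuanxiong", "shengdihuang", "difuzi", "chishao", "fangfeng", "kushen",
      "mahuang", "danggui", "chantui")),
)

# (pinyin, english, latin, usage frequency among the 17 formulas)
PAPER_LEXICON: tuple[tuple[str, str, str, int], ...] = (
    ("difuzi", "Fructus kochiae", "Bassia scoparia (L.) A.J.Scott", 15),
    ("baixianpi", "Densefruit pittany root-bark", "Dictamnus albus L.", 13),
    ("kushen", "Lightyellow sophora", "Sophora flavescens aiton", 13),
    ("danggui", "Chinese angelica", "Angelica sinensis (oliv.) diels", 12),
    ("xixin", "Manchurian wildginger", "Asarum sieboldii miq.", 12),
    ("chantui", "Cicada slough", "Cryptotympana atrata fabr.", 12),
    ("chuanxiong", "Szechuan lovage rhizome", "Ligusticum striatum DC.", 11),
    ("jingjie", "Fineleaf schizonepeta herb", "Nepeta tenuifolia benth", 8),
    ("tufulin", "Rhizoma smilacis glabrae", "Smilax glabra roxb", 8),
    ("dahuang", "Rhubarb root and rhizome", "Rheum officinale baill.", 7),
    ("mahuang", "Ephedra equisetina", "Ephedra sinica stapf", 7),
    ("baizhi", "Dahurian angelica", "Bletilla striata (thunb.) Rchb.f.", 6),
    ("jixueteng", "Suberect spatholobus stem", "Millettia dielsiana harms", 5),
    ("danshen", "Salvia miltiorrhiza f alba", "Salvia miltiorrhiza bunge", 4),
    ("shechuangzi", "Common cnidium", "Cnidium monnieri (L.) cusson", 4),
    ("fangfeng", "Divaricate saposhnikovia",
     "Saposhnikovia divaricata (turcz.) schischk.", 4),
    ("heshouwu", "Tuber fleeceflower",
     "Reynoutria multiflora (Thunb.) moldenke", 3),
    ("zaojiaoci", "Spine of Chinese honeylocust", "Gleditsia sinensis lam.", 3),
    ("baijili", "Tribulus fruit", "Tribulus terrestris L.", 3),
    ("cangzhu", "Atractylodes japonica", "Atractylodes lancea (thunb.) DC.", 2),
    ("guizhi", "Cassiabarktree twig", "Cinnamomum cassia (L.) J.Presl", 2),
    ("honghua", "Safflower", "Carthamus tinctorius L.", 2),
    ("zisuye", "Perilla frutescens var acuta",
     "Perilla frutescens (L.) britton", 2),
    ("songjie", "Knotty pine wood", "Pinus tabuliformis carriere", 2),
    ("chishao", "Red peony root", "Paeonia lactiflora pall.", 2),
    ("qianghuo", "Notopterygium forbesii",
     "Notopterygium incisum K.C.Ting ex H.T.Chang", 2),
    ("tanxiang", "Sandalwood", "Santalum album L.", 2),
    ("haitongpi", "Oriental Variegated coralbean bark",
     "Erythrina variegata L.", 1),
    ("huaizhi", "Twig of Japanese pagodatree",
     "Styphnolobium japonicum (L.) schott", 1),
    ("wugong", "Centipede", "Scolopendra Subspinipes Mutilans", 1),
    ("wushaoshe", "Chinese rat snake", "Zaocys dhumnades cantor", 1),
    ("biejia", "Turtle shell", "Trionyx sinensis wiegmann", 1),
    ("huoxiang", "Wrinkled gianthyssop", "Pogostemon cablin (blanco) benth.", 1),
    ("peilan", "Eupatorium formosanum", "Eupatorium fortunei turcz.", 1),
    ("taoren", "Peach kernel", "Prunus persica (L.) batsch", 1),
    ("juhua", "Florists chrysanthemum flower",
     "Chrysanthemum morifolium ramat.", 1),
    ("wujiapi", "Acanthopanax senticosus",
     "Eleutherococcus nodiflorus (dunn) S.Y.Hu", 1),
    ("shengdihuang", "Fresh rehmannia root",
     "Rehmannia glutinosa (gaertn.) DC.", 1),
    ("weilingxian", "Chinese clematis", "Clematis chinensis osbeck", 1),
    ("quanxie", "Scorpion", "Buthus martensii karsch.", 1),
    ("jixuecao", "Asiatic pennywort", "Centella asiatica (L.) urb.", 1),
    ("taozhi", "Prunus davidiana", "Prunus persica (L.) batsch", 1),
    ("shenjincao", "Common clubmoss herb", "Lycopodium clavatum L.", 1),
)

# The published rule table: (antecedent, consequent, support, confidence,
# expected confidence, lift) as printed, in printed order. Two of the
# expected-confidence cells carry visible rounding noise relative to the
# exact fractions 7/22 and 3/22; they are kept verbatim here and compared
# at a looser tolerance by the replication check.
PAPER_RULES: tuple[tuple[str, str, float, float, float, float], ...] = (
    ("jixueteng", "danggui", 0.13636364, 1.000000, 0.181818182, 5.500000),
    ("jixueteng", "chantui", 0.13636364, 1.000000, 0.318181833, 3.142857),
    ("baixianpi", "difuzi", 0.13636364, 1.000000, 0.181818182, 5.500000),
    ("chuanxiong", "dahuang", 0.09090909, 1.000000, 0.090909091, 11.000000),
    ("dahuang", "chuanxiong", 0.09090909, 1.000000, 0.090909091, 11.000000),
    ("chuanxiong", "baizhi", 0.09090909, 1.000000, 0.136363643, 7.333333),
    ("dahuang", "baizhi", 0.09090909, 1.000000, 0.136363643, 7.333333),
    ("baijili", "baizhi", 0.09090909, 1.000000, 0.136363643, 7.333333),
    ("baijili", "baixianpi", 0.09090909, 1.000000, 0.136363643, 7.333333),
    ("baijili", "danshen", 0.09090909, 1.000000, 0.136363643, 7.333333),
    ("baijili", "difuzi", 0.09090909, 1.000000, 0.181818182, 5.500000),
    ("guizhi", "chantui", 0.09090909, 1.000000, 0.318181833, 3.142857),
    ("songjie", "kushen", 0.09090909, 1.000000, 0.181818182, 5.500000),
    ("chishao", "difuzi", 0.09090909, 1.000000, 0.181818182, 5.500000),
    ("chishao", "kushen", 0.09090909, 1.000000, 0.181818182, 5.500000),
    ("heshouwu", "fangfeng", 0.09090909, 1.000000, 0.136363643, 7.333333),
    ("heshouwu", "jingjie", 0.09090909, 1.000000, 0.181818182, 5.500000),
    ("heshouwu", "kushen", 0.09090909, 1.000000, 0.181818182, 5.500000),
    ("heshouwu", "chantui", 0.09090909, 1.000000, 0.318181833, 3.142857),
)
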