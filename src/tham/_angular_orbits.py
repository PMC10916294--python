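"""Frozen orbit tables for the shipped angular grids.

Solved from the moment equations in tham.angular_design.
Format: ORBITS[n_points] = (degree, [(code, params, weight), ...]).
"""

ORBITS = {
    6: (3, [
        (1, (), 2.0943951023931953),
    ]),
    26: (7, [
        (1, (), 0.5983986006837702),
        (2, (), 0.4787188805470161),
        (3, (), 0.40391905546154483),
    ]),
    110: (17, [
        (1, (), 0.048107465851396476),
        (3, (), 0.12307173528167017),
        (4, (0.59389030736095572,), 0.12058024902852792),
        (4, (1.3531241759027426,), 0.12494509687251337),
        (4, (0.26487957202170842,), 0.10319173408833045),
        (5, (1.0719998179478758,), 0.12183091738552139),
    ]),
    302: (23, [
        (1, (), 0.03125261536346662),
        (3, (), 0.05701900004658199),
        (4, (0.45056851307228074,), 0.03592261688357146),
        (4, (0.71152410380158004,), 0.031643444141118325),
        (4, (1.2528459310534343,), 0.05033452837429951),
        (4, (0.20115661771386104,), 0.05656451001584928),
        (4, (0.72237665373294102,), 0.029908111314044333),
        (4, (1.2505372431931534,), 0.01503052419379593),
        (4, (0.36898847219341141,), 0.017917713549026895),
        (5, (0.37778964149245825,), 0.0684312426043787),
        (6, (0.56082883927847682, 1.1416158021481166), 0.051887883465646635),
        (6, (0.90786106660143262, 0.10857069950984773), 0.043625415200596616),
    ]),
    590: (31, [
        (1, (), 0.04164169418376062),
        (3, (), 0.01089471379449005),
        (4, (0.18935959378297881,), 0.014391430726882462),
        (4, (0.51259724957789743,), 0.01727576280520004),
        (4, (1.3767056763426246,), 0.03680447442168184),
        (4, (0.82834911933643529,), 0.03233469252260043),
        (4, (0.26993905531826307,), 0.008857197264487127),
        (4, (0.67216000093770867,), 0.0023255882898899384),
        (4, (0.61535069391838704,), 0.023120665404578338),
        (4, (0.37196544561142508,), 0.018027303484566905),
        (4, (1.1931110220204855,), 0.002939405521191313),
        (5, (0.41547044227851354,), 0.03364623576623264),
        (5, (0.59889324175580771,), 0.030374082265118365),
        (5, (0.79764993091333392,), 0.018181116146718492),
        (6, (0.79551735018524139, 1.0216449532100724), 0.018974100419744087),
        (6, (0.98289120653210038, 1.3758024609885744), 0.02885449710295563),
        (6, (0.42703377849085489, 1.1408378415118021), 0.03096926730375118),
        (6, (0.99435331997835152, 0.43011730111003255), 0.017974338820365542),
        (6, (0.2323613460677168, 1.3102263811058952), 0.022738983604868323),
        (6, (0.59087446195437832, 0.48887403466054824), 0.016128225832505266),
    ]),
    5810: (65, [
        (1, (), 0.0008991032122744806),
        (2, (), 0.0015349220228701825),
        (3, (), 0.0004684717272714694),
        (4, (0.050000000000000003,), 0.002355503807193626),
        (4, (0.17256636056624136,), 0.0023498956685360658),
        (4, (0.29513272113248273,), 0.001393249137630581),
        (4, (0.41769908169872411,), 0.0008014748883451839),
        (4, (0.54026544226496553,), 0.0009815736868325905),
        (4, (0.66283180283120691,), 0.0021496038024514945),
        (4, (0.78539816339744828,), 0.001557725265485602),
        (4, (0.90796452396368965,), 0.0032677038368470485),
        (4, (1.030530884529931,), 0.0007855397187152762),
        (4, (1.1530972450961723,), 0.002003708931910698),
        (4, (1.2756636056624138,), 0.0012373897760306477),
        (4, (1.3982299662286553,), 0.0009869414178557123),
        (4, (1.5207963267948965,), 0.0015855869768164525),
        (5, (0.050000000000000003,), 0.000786601767533035),
        (5, (0.11230892394522257,), 0.003081689160170879),
        (5, (0.17461784789044513,), 0.0006787115484581654),
        (5, (0.23692677183566768,), 0.0003822535040054363),
        (5, (0.29923569578089027,), 0.0009991087747283764),
        (5, (0.36154461972611279,), 0.0017403093801326313),
        (5, (0.42385354367133538,), 0.0018614237490033757),
        (5, (0.4861624676165579,), 0.004106914898345645),
        (5, (0.54847139156178049,), 0.0011633986722682438),
        (5, (0.61078031550700307,), 0.0011351548165678535),
        (5, (0.67308923945222565,), 0.003258072840378991),
        (5, (0.73539816339744823,), 0.0016346725812274579),
        (6, (1.2551492310326902, 0.54809081641726554), 0.0022114163198390276),
        (6, (1.5397262856652925, 0.066003174972224937), 0.0017998038034021874),
        (6, (1.539901367496223, 0.75988878661232295), 0.00147823756663223),
        (6, (0.99321290854236843, 0.75971257016767102), 0.0008359225037904507),
        (6, (1.5398367594539653, 0.38870055801050712), 0.0023495776972582245),
        (6, (1.3116057544630757, 0.30202120529783244), 0.002317604732555415),
        (6, (1.3201504898930172, 0.76341271702052405), 0.003123003886606488),
        (6, (1.4591841411499733, 0.57523294229425492), 0.0020954493818934232),
        (6, (1.4703133126658956, 0.22751711872548935), 0.00316776586738182),
        (6, (1.1578950723904391, 0.70419706227965817), 0.0031280631206150656),
        (6, (1.3818257828636247, 0.4412676406838385), 0.003905139089332096),
        (6, (1.1149815526397813, 0.55369595708990094), 0.002458279163349008),
        (6, (1.2264766711571338, 0.40992697187997257), 0.0026431525041325657),
        (6, (1.3474459332619499, 0.63549232982685), 0.002241881513042397),
        (6, (1.4312028862190753, 0.71707254364645245), 0.0039968210288357005),
        (6, (1.4341613428589015, 0.33750181512845884), 0.0025545573016416854),
        (6, (1.5406445757768739, 0.64876794740973054), 0.0015881141782314655),
        (6, (1.5380328965018366, 0.49998793650240381), 0.0010587793056388943),
        (6, (1.0583087978367058, 0.65826027908915896), 0.003012750421942553),
        (6, (1.2478733396265393, 0.65382228590996083), 0.002667838864834564),
        (6, (1.3524394229768157, 0.53645308516598422), 0.0038931331349064137),
        (6, (1.5398975844558607, 0.16123543901614398), 0.0028440661652244146),
        (6, (1.5406528997108713, 0.28937341865154487), 0.003133255562001496),
        (6, (1.3782214623273634, 0.22997175446654367), 0.001100086060112002),
        (6, (1.0823261867304668, 0.75699137940189309), 0.0028351685177455455),
        (6, (1.2284601790085932, 0.760816745604874), 0.0030436216298407293),
        (6, (1.4700699088494733, 0.44437050874540529), 0.003240545390047577),
        (6, (1.2974299304960164, 0.46613467107471124), 0.0034024527295015822),
        (6, (1.1841098462868622, 0.49421796076411245), 0.003929384429143114),
        (6, (1.4591649271921792, 0.14545952396682249), 0.0013438838780103516),
        (6, (1.1781860302542129, 0.60960996264639511), 0.0029153550022983266),
        (6, (1.3207534395075187, 0.38394668646808833), 0.003183428805192878),
        (6, (1.4240465270974405, 0.50642782348997872), 0.0018422850071853013),
        (6, (1.4242608500852305, 0.64213857900386273), 0.0026707353440924507),
        (6, (1.5396132446889756, 0.57283644289448543), 0.002716104257353538),
        (6, (1.3596177467203179, 0.70495885264111124), 0.004036447792345894),
        (6, (1.4998878765336261, 0.70383156792946466), 0.0037274643349188676),
        (6, (1.3794155836920619, 0.30027088382605549), 0.002084942687034659),
        (6, (1.2904026356551208, 0.70427178725554163), 0.003302488451402497),
        (6, (1.5370479300163442, 0.22544935710329364), 0.003940752461478547),
        (6, (1.4988674642102644, 0.33738463256809076), 0.0026763602485109354),
        (6, (1.1225866362072421, 0.64331543539005165), 0.0029420421840469953),
        (6, (1.3074866090474238, 0.58497457158064381), 0.003796592474577623),
        (6, (1.3896378139729553, 0.58804396443619367), 0.0009852212895502428),
        (6, (1.385391056158384, 0.3775197418131479), 0.0033372594040740897),
        (6, (1.477315294941044, 0.76338877327928767), 0.002909510847055249),
        (6, (1.3868410798979949, 0.76251045753053215), 0.002616914427064273),
        (6, (1.2665615030957289, 0.35448193678026252), 0.0028673324939096365),
        (6, (1.4329765278666751, 0.27451818612406187), 0.002154517788009934),
        (6, (1.4831873029950233, 0.52073205191598648), 0.003448647273800536),
        (6, (1.4832160247512456, 0.63729298152791036), 0.0037072941234277453),
        (6, (1.4230761817026762, 0.19202622547020637), 0.0036968466836745173),
        (6, (1.2396648155625736, 0.47462371334294229), 0.0012882954432747876),
        (6, (1.5069088202273913, 0.11290386619183473), 0.003652708864262797),
        (6, (1.4660969317269532, 0.38505257742942595), 0.0029361612321437067),
        (6, (1.2148889867624457, 0.70221852436033338), 0.0030129163776982837),
        (6, (1.1990550625723504, 0.55313165700155664), 0.0023621288219666495),
        (6, (1.5320976478731658, 0.44419484786581098), 0.0018610061863447841),
        (6, (1.1717253200645872, 0.76210674385121413), 0.0016484370892522074),
        (6, (1.0374312025302821, 0.71651784377277439), 0.003435343716646497),
        (6, (1.2311724125420542, 0.59958507855031473), 0.0031968855147720505),
        (6, (1.4886357816620859, 0.27789451478530819), 0.002420417994441583),
        (6, (1.0822083304002323, 0.60434632978667402), 0.0015708819189417273),
        (6, (1.1051251613354902, 0.69948732904973365), 0.0025336718996861944),
        (6, (1.3478310892090299, 0.48319773255686377), 0.001790364708592013),
        (6, (1.3006139491072743, 0.52009074028576197), 0.0014029366065668066),
        (6, (1.2979554767069277, 0.64729630154256323), 0.0021551797636659917),
        (6, (1.4937068114081251, 0.18213454869576987), 0.002657874616846103),
        (6, (1.2768781166588399, 0.41840189682917839), 0.0030659740252372615),
        (6, (1.4270906083918646, 0.41900265434036821), 0.0011927252866666888),
        (6, (1.3514385939064699, 0.34126537178834998), 0.0020404310456374284),
        (6, (1.3340836427000173, 0.43205608264715167), 0.0010774049559053203),
        (6, (1.3443017231150025, 0.2664163633492696), 0.002076898310261975),
        (6, (1.1881786221266923, 0.65942636728313486), 0.0020495392097195603),
        (6, (1.1276967483352118, 0.74516279207858027), 0.0015805354635652995),
        (6, (1.2754908275122694, 0.75032047800007962), 0.0009222326800197761),
        (6, (1.4609094326848806, 0.67914012449937977), 0.0011554806466832544),
        (6, (1.3976922915944221, 0.67940101818056409), 0.0009113473305685213),
        (6, (1.4997247386170245, 0.59509149264193895), 0.001697825163446371),
        (6, (1.416254542398484, 0.55114177934347919), 0.0035143305907889945),
        (6, (1.1966514551740355, 0.44798828555406134), 0.002051759257215174),
        (6, (1.1553401088377624, 0.53113312986669725), 0.0012923211894484915),
        (6, (1.5004013579410098, 0.47668369978352609), 0.0011322787434654156),
        (6, (1.5007101642852325, 0.41158142508119122), 0.0017019358703399246),
        (6, (1.4312178656753258, 0.76042124540440936), 0.0008568306883088909),
        (6, (1.4275654340511754, 0.46319623487594935), 0.0009605219877569427),
        (6, (1.134120200968842, 0.59612893170113457), 0.0022771433261370012),
        (6, (1.2735957521340884, 0.61145735764177811), 0.0009807321303242978),
        (6, (1.5406542669811527, 0.71311318432502702), 0.0014776612338061057),
        (6, (1.5400960616577972, 0.34409805910256069), 0.0014523237334557557),
        (6, (1.2234835549913918, 0.51710025985866792), 0.0007493801837087213),
        (6, (1.3894982392506827, 0.48320030581273676), 0.001668721364877312),
        (6, (1.3294580220474157, 0.67486247386761211), 0.0011049025660607498),
        (6, (1.3482866709423562, 0.58270164677939318), 0.001093211202573631),
        (6, (1.4262102612924195, 0.23305571361840974), 0.0005908803642944254),
        (6, (1.4644998298793426, 0.31038146425207414), 0.0017788624928231557),
        (6, (1.3090915352838755, 0.34409260371591727), 0.0008368415943108492),
        (6, (1.461171379320173, 0.48501403836821733), 0.0010182404016233501),
        (6, (1.4276152922586292, 0.59986064543180451), 0.0011703997332768539),
        (6, (1.5193554967359688, 0.53702204394368591), 0.0016504258280228639),
        (6, (1.3867718325091996, 0.63008867100410137), 0.002562371031271341),
        (6, (1.4277956951691722, 0.37778482034031763), 0.0007485928102413194),
        (6, (1.3909964094142075, 0.3388292370394842), 0.0009099577868939966),
        (6, (1.2526082427078229, 0.71157294801031279), 0.0010353891828918877),
        (6, (1.2644067965982455, 0.50775047055553879), 0.0024536250135567747),
        (6, (1.0393542203723447, 0.76045445287964786), 0.0008154614683649991),
        (6, (1.3943537976902722, 0.26448216570477828), 0.002334953704310564),
        (6, (1.5346738444861576, 0.6118188844612511), 0.0012091269854940044),
    ]),
}
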