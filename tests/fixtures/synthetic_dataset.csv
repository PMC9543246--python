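cell_line,drug,species,analyte,replicate,time_h,value
synthetic,synthetic-drug,MYC,mRNA,0,0.0,0.9599706406185823
synthetic,synthetic-drug,MYC,mRNA,0,4.0,0.22735618641918348
synthetic,synthetic-drug,MYC,mRNA,0,8.0,0.22550196411285012
synthetic,synthetic-drug,MYC,mRNA,0,24.0,0.19099413361259635
synthetic,synthetic-drug,MYC,mRNA,0,48.0,0.17901869635113507
synthetic,synthetic-drug,MYC,mRNA,0,72.0,0.15117081221238005
synthetic,synthetic-drug,MYC,mRNA,1,0.0,0.9083187321901603
synthetic,synthetic-drug,MYC,mRNA,1,4.0,0.18431338654876958
synthetic,synthetic-drug,MYC,mRNA,1,8.0,0.1775752624876242
synthetic,synthetic-drug,MYC,mRNA,1,24.0,0.2030165360508759
synthetic,synthetic-drug,MYC,mRNA,1,48.0,0.17081218373466628
synthetic,synthetic-drug,MYC,mRNA,1,72.0,0.16078043361852212
synthetic,synthetic-drug,MYC,mRNA,2,0.0,0.933501156070229
synthetic,synthetic-drug,MYC,mRNA,2,4.0,0.18089892513760192
synthetic,synthetic-drug,MYC,mRNA,2,8.0,0.17400653383292755
synthetic,synthetic-drug,MYC,mRNA,2,24.0,0.1701448860311366
synthetic,synthetic-drug,MYC,mRNA,2,48.0,0.18235338764512132
synthetic,synthetic-drug,MYC,mRNA,2,72.0,0.15902844388348233
synthetic,synthetic-drug,MYC,protein,0,0.0,0.9507170868597863
synthetic,synthetic-drug,MYC,protein,0,4.0,0.21390186465917324
synthetic,synthetic-drug,MYC,protein,0,8.0,0.17068713057895424
synthetic,synthetic-drug,MYC,protein,0,24.0,0.20971152374369517
synthetic,synthetic-drug,MYC,protein,0,48.0,0.1524887060023793
synthetic,synthetic-drug,MYC,protein,0,72.0,0.1598087095619355
synthetic,synthetic-drug,MYC,protein,1,0.0,1.2314483312607303
synthetic,synthetic-drug,MYC,protein,1,4.0,0.16984750680421096
synthetic,synthetic-drug,MYC,protein,1,8.0,0.1710344067729399
synthetic,synthetic-drug,MYC,protein,1,24.0,0.17256604209424234
synthetic,synthetic-drug,MYC,protein,1,48.0,0.17417417280868341
synthetic,synthetic-drug,MYC,protein,1,72.0,0.13411379736217716
synthetic,synthetic-drug,MYC,protein,2,0.0,0.9719561292168989
synthetic,synthetic-drug,MYC,protein,2,4.0,0.2184484318657904
synthetic,synthetic-drug,MYC,protein,2,8.0,0.2001807430823716
synthetic,synthetic-drug,MYC,protein,2,24.0,0.14616369796387102
synthetic,synthetic-drug,MYC,protein,2,48.0,0.18362808448857387
synthetic,synthetic-drug,MYC,protein,2,72.0,0.18661350283759162
synthetic,synthetic-drug,IRF4,mRNA,0,0.0,1.0393299111826144
synthetic,synthetic-drug,IRF4,mRNA,0,4.0,0.6050699103234408
synthetic,synthetic-drug,IRF4,mRNA,0,8.0,0.38535169134131836
synthetic,synthetic-drug,IRF4,mRNA,0,24.0,0.22360152851793394
synthetic,synthetic-drug,IRF4,mRNA,0,48.0,0.25211874700238784
synthetic,synthetic-drug,IRF4,mRNA,0,72.0,0.22804137702320354
synthetic,synthetic-drug,IRF4,mRNA,1,0.0,1.0617084736809337
synthetic,synthetic-drug,IRF4,mRNA,1,4.0,0.4832285328939642
synthetic,synthetic-drug,IRF4,mRNA,1,8.0,0.39262519198957485
synthetic,synthetic-drug,IRF4,mRNA,1,24.0,0.28817799161593627
synthetic,synthetic-drug,IRF4,mRNA,1,48.0,0.22910619615848293
synthetic,synthetic-drug,IRF4,mRNA,1,72.0,0.21760024497868005
synthetic,synthetic-drug,IRF4,mRNA,2,0.0,0.8361310653999573
synthetic,synthetic-drug,IRF4,mRNA,2,4.0,0.6053935420500332
synthetic,synthetic-drug,IRF4,mRNA,2,8.0,0.4347436902615836
synthetic,synthetic-drug,IRF4,mRNA,2,24.0,0.3213994717660267
synthetic,synthetic-drug,IRF4,mRNA,2,48.0,0.24451839193895217
synthetic,synthetic-drug,IRF4,mRNA,2,72.0,0.21807947921244666
synthetic,synthetic-drug,IRF4,protein,0,0.0,1.0480320652372193
synthetic,synthetic-drug,IRF4,protein,0,4.0,0.8884401701065446
synthetic,synthetic-drug,IRF4,protein,0,8.0,1.092637165292474
synthetic,synthetic-drug,IRF4,protein,0,24.0,0.7880429577218431
synthetic,synthetic-drug,IRF4,protein,0,48.0,0.5636813562694934
synthetic,synthetic-drug,IRF4,protein,0,72.0,0.5562217959954602
synthetic,synthetic-drug,IRF4,protein,1,0.0,1.1924391277314952
synthetic,synthetic-drug,IRF4,protein,1,4.0,1.0866007012014365
synthetic,synthetic-drug,IRF4,protein,1,8.0,1.0608273745744916
synthetic,synthetic-drug,IRF4,protein,1,24.0,0.8447241324545793
synthetic,synthetic-drug,IRF4,protein,1,48.0,0.518662493141374
synthetic,synthetic-drug,IRF4,protein,1,72.0,0.5698118505325006
synthetic,synthetic-drug,IRF4,protein,2,0.0,1.0107963099850754
synthetic,synthetic-drug,IRF4,protein,2,4.0,0.7587518671529705
synthetic,synthetic-drug,IRF4,protein,2,8.0,0.8999110993305132
synthetic,synthetic-drug,IRF4,protein,2,24.0,0.7591838058734188
synthetic,synthetic-drug,IRF4,protein,2,48.0,0.7372962099651278
synthetic,synthetic-drug,IRF4,protein,2,72.0,0.5390344141068565
synthetic,synthetic-drug,PRDM1,mRNA,0,0.0,1.0250822638871981
synthetic,synthetic-drug,PRDM1,mRNA,0,4.0,1.0183257537852008
synthetic,synthetic-drug,PRDM1,mRNA,0,8.0,0.8636170983839914
synthetic,synthetic-drug,PRDM1,mRNA,0,24.0,0.754433387484484
synthetic,synthetic-drug,PRDM1,mRNA,0,48.0,0.8133458722919895
synthetic,synthetic-drug,PRDM1,mRNA,0,72.0,0.6853251007475787
synthetic,synthetic-drug,PRDM1,mRNA,1,0.0,0.9936237181967594
synthetic,synthetic-drug,PRDM1,mRNA,1,4.0,0.9776074806897195
synthetic,synthetic-drug,PRDM1,mRNA,1,8.0,0.9380537624094298
synthetic,synthetic-drug,PRDM1,mRNA,1,24.0,0.9699471286174515
synthetic,synthetic-drug,PRDM1,mRNA,1,48.0,0.824345924554634
synthetic,synthetic-drug,PRDM1,mRNA,1,72.0,0.6631656932360248
synthetic,synthetic-drug,PRDM1,mRNA,2,0.0,0.8232764506640592
synthetic,synthetic-drug,PRDM1,mRNA,2,4.0,0.7676586729690696
synthetic,synthetic-drug,PRDM1,mRNA,2,8.0,0.8539667261725252
synthetic,synthetic-drug,PRDM1,mRNA,2,24.0,0.9037696030460618
synthetic,synthetic-drug,PRDM1,mRNA,2,48.0,0.8856805369635551
synthetic,synthetic-drug,PRDM1,mRNA,2,72.0,0.6767258156530535
synthetic,synthetic-drug,PRDM1,protein,0,0.0,1.064578112312663
synthetic,synthetic-drug,PRDM1,protein,0,4.0,1.1170958701373837
synthetic,synthetic-drug,PRDM1,protein,0,8.0,1.2596570320187186
synthetic,synthetic-drug,PRDM1,protein,0,24.0,0.9824529004991754
synthetic,synthetic-drug,PRDM1,protein,0,48.0,0.990589891534045
synthetic,synthetic-drug,PRDM1,protein,0,72.0,0.7664127603203499
synthetic,synthetic-drug,PRDM1,protein,1,0.0,0.8793857174619522
synthetic,synthetic-drug,PRDM1,protein,1,4.0,0.7932961195594841
synthetic,synthetic-drug,PRDM1,protein,1,8.0,1.023353044621487
synthetic,synthetic-drug,PRDM1,protein,1,24.0,1.0431948208112112
synthetic,synthetic-drug,PRDM1,protein,1,48.0,1.0917888821011386
synthetic,synthetic-drug,PRDM1,protein,1,72.0,0.7004210163151653
synthetic,synthetic-drug,PRDM1,protein,2,0.0,1.0448968934101275
synthetic,synthetic-drug,PRDM1,protein,2,4.0,0.983521522364306
synthetic,synthetic-drug,PRDM1,protein,2,8.0,0.7844151638295883
synthetic,synthetic-drug,PRDM1,protein,2,24.0,0.9910891763390892
synthetic,synthetic-drug,PRDM1,protein,2,48.0,0.8264460827242678
synthetic,synthetic-drug,PRDM1,protein,2,72.0,0.6591942436005315
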