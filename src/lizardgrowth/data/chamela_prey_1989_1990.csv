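year,season,category,life_stage,count
1989,wet,Aranae,unspecified,121
1989,wet,Coleoptera,adult,49
1989,wet,Coleoptera,larva,6
1989,wet,Diptera,unspecified,31
1989,wet,Hemiptera,unspecified,25
1989,wet,Homoptera,unspecified,14
1989,wet,Hymenoptera,unspecified,40
1989,wet,Isoptera,unspecified,1
1989,wet,Lepidoptera,larva,11
1989,wet,Orthoptera,unspecified,43
1989,dry,Acaridae,unspecified,1
1989,dry,Aranae,unspecified,40
1989,dry,Coleoptera,adult,8
1989,dry,Coleoptera,larva,1
1989,dry,Diptera,unspecified,3
1989,dry,Hemiptera,unspecified,5
1989,dry,Homoptera,unspecified,6
1989,dry,Hymenoptera,unspecified,13
1989,dry,Lepidoptera,adult,2
1989,dry,Orthoptera,unspecified,5
1990,wet,Aranae,unspecified,88
1990,wet,Coleoptera,adult,29
1990,wet,Coleoptera,larva,3
1990,wet,Diptera,unspecified,29
1990,wet,Hemiptera,unspecified,25
1990,wet,Homoptera,unspecified,66
1990,wet,Hymenoptera,unspecified,54
1990,wet,Lepidoptera,adult,19
1990,wet,Lepidoptera,larva,8
1990,wet,Orthoptera,unspecified,33
1990,wet,Thysanoptera,unspecified,2
1990,dry,Aranae,unspecified,79
1990,dry,Coleoptera,adult,11
1990,dry,Coleoptera,larva,1
1990,dry,Dermaptera,unspecified,1
1990,dry,Diptera,unspecified,8
1990,dry,Hemiptera,unspecified,7
1990,dry,Homoptera,unspecified,14
1990,dry,Hymenoptera,unspecified,7
1990,dry,Lepidoptera,larva,2
1990,dry,Orthoptera,unspecified,23
1990,dry,Psocoptera,unspecified,1
1990,dry,Thysanoptera,unspecified,1
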